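"""Panel readers/writers, the synthetic panel generator, index containers.

Supported inputs are plain-text 0/1 matrices (one haplotype per row by
default; ``transpose`` for site-major files) and phased VCF, where every
sample contributes two haplotypes named ``<sample>_0`` / ``<sample>_1``.
VCF loading mirrors the usual biallelic-SNP filter: records with more than
one ALT or with non-ACGT alleles are skipped (and counted); a missing or
unphased genotype aborts the load with the offending site and sample named,
because half-calls cannot be placed in a haplotype panel.

The on-disk index container is versioned JSON holding the per-column run
pairs, the boundary samples and the haplotype name table.
"""

from __future__ import annotations

import json
import logging
import os
from typing import IO, Iterable, List, Sequence, Tuple, Union

import numpy as np

from .dynamic_index import DynIndex
from .match_query import Match, sort_matches

log = logging.getLogger("pbwtree")

PathLike = Union[str, os.PathLike]


# ---------------------------------------------------------------- matrices


def read_matrix(path: PathLike, transpose: bool = False) -> np.ndarray:
    """Read a plain 0/1 text matrix (rows = haplotypes unless ``transpose``)."""
    rows: List[List[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip().replace(" ", "").replace("\t", "")
            if not line or line.startswith("#"):
                continue
            try:
                rows.append([{"0": 0, "1": 1}[c] for c in line])
            except KeyError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-binary symbol {exc.args[0]!r}"
                ) from None
    if rows and len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: ragged matrix")
    arr = np.array(rows, dtype=np.int8)
    if arr.size == 0:
        arr = arr.reshape(0, 0)
    return arr.T.copy() if transpose else arr


def write_matrix(path: PathLike, panel, transpose: bool = False) -> None:
    arr = np.asarray(panel, dtype=np.int8)
    if transpose:
        arr = arr.T
    with open(path, "w") as fh:
        for row in arr:
            fh.write("".join(str(int(b)) for b in row) + "\n")


# --------------------------------------------------------------------- VCF


def read_vcf(path: PathLike) -> Tuple[np.ndarray, List[str]]:
    """Load phased biallelic SNPs from a VCF into a haplotype panel.

    Returns ``(panel, names)`` with two haplotypes per sample.  Non-SNP and
    multi-allelic records are skipped (count logged); unphased or missing
    genotypes raise a :class:`ValueError`.
    """
    import pysam

    bases = {"A", "C", "G", "T"}
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        columns: List[List[int]] = []
        skipped = 0
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or rec.ref.upper() not in bases
                or alts[0].upper() not in bases
            ):
                skipped += 1
                continue
            col: List[int] = []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or len(gt) != 2 or None in gt:
                    raise ValueError(
                        f"{path}: missing genotype at {rec.chrom}:{rec.pos} "
                        f"for sample {s}"
                    )
                if not call.phased:
                    raise ValueError(
                        f"{path}: unphased genotype at {rec.chrom}:{rec.pos} "
                        f"for sample {s}"
                    )
                if gt[0] not in (0, 1) or gt[1] not in (0, 1):
                    raise ValueError(
                        f"{path}: non-biallelic allele index at "
                        f"{rec.chrom}:{rec.pos} for sample {s}"
                    )
                col.extend((gt[0], gt[1]))
            columns.append(col)
    if skipped:
        log.info("%s: skipped %d non-biallelic/non-SNP records", path, skipped)
    names = [f"{s}_{i}" for s in samples for i in (0, 1)]
    if not columns:
        return np.zeros((len(names), 0), dtype=np.int8), names
    return np.array(columns, dtype=np.int8).T.copy(), names


# ---------------------------------------------------------------- generator


def generate_panel(
    M: int,
    N: int,
    seed: int,
    mutation_density: float = 0.02,
    recomb_rate: float = 0.01,
    founders: int = 4,
) -> np.ndarray:
    """Synthesize an ``M x N`` panel with realistic run structure.

    Haplotypes beyond a small founder set are mosaic copies of earlier
    haplotypes: a copying template that switches at rate ``recomb_rate`` per
    site, plus independent flips at ``mutation_density`` per site.  Shared
    ancestry keeps PBWT run counts far below ``M`` — the regime run-length
    compression targets.  Deterministic for a fixed seed.
    """
    if M < 1 or N < 1:
        raise ValueError(f"panel dimensions must be positive, got {M}x{N}")
    if not 0.0 <= mutation_density <= 1.0 or not 0.0 <= recomb_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    if founders < 1:
        raise ValueError("need at least one founder")
    rng = np.random.default_rng(seed)
    F = min(founders, M)
    panel = np.empty((M, N), dtype=np.int8)
    panel[:F] = rng.integers(0, 2, (F, N), dtype=np.int8)
    for i in range(F, M):
        src = int(rng.integers(0, i))
        switch = rng.random(N) < recomb_rate
        hap = np.empty(N, dtype=np.int8)
        for k in range(N):
            if switch[k]:
                src = int(rng.integers(0, i))
            hap[k] = panel[src, k]
        flip = rng.random(N) < mutation_density
        hap[flip] ^= 1
        panel[i] = hap
    return panel


# ------------------------------------------------------------- index files


def save_index(path: PathLike, index: DynIndex, names: Sequence[str]) -> None:
    """Write the versioned JSON index container."""
    if len(names) != index.M:
        raise ValueError(f"{len(names)} names for {index.M} haplotypes")
    payload = index.to_dict()
    payload["hap_names"] = list(names)
    with open(path, "w") as fh:
        json.dump(payload, fh, separators=(",", ":"))


def load_index(path: PathLike) -> Tuple[DynIndex, List[str]]:
    with open(path) as fh:
        payload = json.load(fh)
    index = DynIndex.from_dict(payload)
    names = payload.get("hap_names") or [f"h{i}" for i in range(index.M)]
    return index, names


def default_names(M: int) -> List[str]:
    return [f"h{i}" for i in range(M)]


# ------------------------------------------------------------ match report


def write_matches_tsv(
    out: Union[PathLike, IO[str]],
    matches: Iterable[Match],
    query_id: str = "-",
    names: Sequence[str] = (),
) -> None:
    """TSV match report: query_id, hap_id, start, end, length."""

    def emit(fh: IO[str]) -> None:
        fh.write("query_id\thap_id\tstart\tend\tlength\n")
        for m in sort_matches(matches):
            hap = names[m.hap_id] if m.hap_id < len(names) else str(m.hap_id)
            fh.write(f"{query_id}\t{hap}\t{m.start}\t{m.end}\t{m.length}\n")

    if hasattr(out, "write"):
        emit(out)  # type: ignore[arg-type]
    else:
        with open(out, "w") as fh:
            emit(fh)
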