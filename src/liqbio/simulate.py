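"""Synthetic triplicate amplicon sequencing with known ground truth.

Two tiers:

* **count-level** — a replicate's mutant read count is one binomial draw at
  the assay's working coverage (default 500,000x per amplicon per
  replicate), with the background modelled as the probability that a
  wild-type molecule is read as the specific alt allele *after* exact-flank
  filtering (``alt_error_rate``, default 1e-5). This tier is fast enough to
  run calibration and calling at full coverage.
* **read-level** — actual FASTQ records: replicate tag + WT or mutant
  template, then uniform per-base substitution noise (default 1e-3).
  A single substitution anywhere in a template breaks at least one exact
  window and sends the read to UNCLASSIFIED downstream, so this tier
  exercises demultiplexing and classification end to end at reduced
  coverage.

Read IDs encode the ground truth (``sim:<marker>:<rep>:<i>:<MUT|WT>``) so
tests can compare realized against classified fractions exactly. Same seed,
same output, at both tiers.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from .amplicon import AmpliconRef, TagSet
from .quantify import ReplicateCount

__all__ = [
    "SimConfig", "FastqRead", "simulate_replicate_counts",
    "simulate_sample_counts", "simulate_reads", "simulate_control_cohort",
    "write_fastq", "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for one simulated marker/sample.

    ``alt_error_rate`` is the post-filter background at the variant
    position; ``per_base_error`` only applies to read-level simulation.
    """

    true_vaf: float
    coverage: int = 500_000
    alt_error_rate: float = 1e-5
    per_base_error: float = 1e-3
    seed: int = 0
    n_replicates: int = 3

    def __post_init__(self):
        if not 0 <= self.true_vaf <= 1:
            raise ValueError(f"true_vaf must be in [0,1], got {self.true_vaf}")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        for name in ("alt_error_rate", "per_base_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    quality: str


def simulate_replicate_counts(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    marker_id: str = "marker",
    replicate: int = 1,
) -> ReplicateCount:
    """One count-level replicate: ``n_mut ~ Binomial(coverage, p)`` with
    ``p = true_vaf + (1 - true_vaf) * alt_error_rate``; everything else is
    wild-type (no unclassified reads at count level)."""
    if rng is None:
        rng = cfg.rng()
    p = cfg.true_vaf + (1.0 - cfg.true_vaf) * cfg.alt_error_rate
    n_mut = int(rng.binomial(cfg.coverage, p))
    return ReplicateCount(
        marker_id=marker_id, replicate=replicate,
        n_wt=cfg.coverage - n_mut, n_mut=n_mut, n_unclassified=0,
    )


def simulate_sample_counts(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    marker_id: str = "marker",
) -> list[ReplicateCount]:
    """A triplicate (or n-replicate) set of count-level draws."""
    if rng is None:
        rng = cfg.rng()
    return [simulate_replicate_counts(cfg, rng, marker_id, rep)
            for rep in range(1, cfg.n_replicates + 1)]


def _mutate_reads(seqs: np.ndarray, per_base_error: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply uniform substitution noise to a (n_reads, L) byte matrix."""
    if per_base_error <= 0:
        return seqs
    hits = rng.random(seqs.shape) < per_base_error
    n = int(hits.sum())
    if n:
        # substitute to one of the three OTHER bases, uniformly
        current = seqs[hits]
        shift = rng.integers(1, 4, size=n)
        idx = np.empty(n, dtype=np.int64)
        for i, b in enumerate(_BASES):
            idx[current == b] = i
        seqs[hits] = _BASES[(idx + shift) % 4]
    return seqs


def simulate_reads(
    amplicon: AmpliconRef,
    tagset: TagSet,
    replicate: int,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[FastqRead]:
    """Read-level simulation of one replicate for one amplicon.

    Each of ``cfg.coverage`` reads is the replicate tag followed by the
    mutant template with probability ``true_vaf`` (else the wild-type),
    with per-base substitution noise applied to the whole read (tag
    included). Quality strings are constant; classification downstream is
    match-based, not quality-based.
    """
    if rng is None:
        rng = cfg.rng()
    tag = tagset.tag(replicate)
    is_mut = rng.random(cfg.coverage) < cfg.true_vaf
    wt = np.frombuffer((tag + amplicon.wt_seq).encode(), dtype="S1")
    mut = np.frombuffer((tag + amplicon.mut_seq).encode(), dtype="S1")

    reads: list[FastqRead] = []
    for truth, template in ((False, wt), (True, mut)):
        n = int((is_mut == truth).sum())
        if n == 0:
            continue
        block = np.tile(template, (n, 1))
        block = _mutate_reads(block, cfg.per_base_error, rng)
        label = "MUT" if truth else "WT"
        qual = "I" * block.shape[1]
        indices = np.flatnonzero(is_mut == truth)
        for row, i in zip(block, indices):
            reads.append(FastqRead(
                name=f"sim:{amplicon.marker_id}:{replicate}:{int(i)}:{label}",
                sequence=row.tobytes().decode(),
                quality=qual,
            ))
    # marker ids may themselves contain ':'; the per-read index is the
    # second-to-last field
    reads.sort(key=lambda r: int(r.name.rsplit(":", 2)[1]))
    return reads


def simulate_control_cohort(
    amplicons: Sequence[AmpliconRef],
    cfg: SimConfig,
    n_donors: int = 3,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, list[ReplicateCount]]:
    """Healthy-donor background runs used for LOD calibration.

    Returns, per marker, ``n_donors * n_replicates`` count-level replicates
    drawn at ``true_vaf = 0`` (the donors carry no tumor variant); with the
    default three donors and triplicates this is the nine-point background
    per marker.
    """
    if rng is None:
        rng = cfg.rng()
    null_cfg = replace(cfg, true_vaf=0.0)
    table: dict[str, list[ReplicateCount]] = {}
    for amp in amplicons:
        points: list[ReplicateCount] = []
        for _donor in range(n_donors):
            points.extend(simulate_sample_counts(null_cfg, rng, amp.marker_id))
        table[amp.marker_id] = points
    return table


# ---------------------------------------------------------------------------
# FASTQ / truth table output

def write_fastq(reads: Iterable[FastqRead], path: Union[str, Path]) -> None:
    """Write standard 4-line FASTQ; gzip if the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth_tsv(rows: Iterable[dict], path: Union[str, Path]) -> None:
    """Truth table: ``marker replicate true_vaf coverage seed`` per row."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("marker\treplicate\ttrue_vaf\tcoverage\tseed\n")
        for row in rows:
            fh.write(f"{row['marker']}\t{row['replicate']}\t"
                     f"{row['true_vaf']}\t{row['coverage']}\t{row['seed']}\n")
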