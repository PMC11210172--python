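"""Demultiplexing and exact-match read classification.

A read is assigned to a replicate by an exact match of its leading bases
against the replicate tags, and to an amplicon by matching the amplicon's
wild-type or mutant template. Classification is by exact window
containment: a read is WT when it contains, as a contiguous substring, the
reference allele with at least ``min_flank`` (default 15) perfectly
matching bases on each side, and MUT for the analogous window around the
alternate allele. Reads matching neither window — or, for degenerate
alleles, both — are UNCLASSIFIED. The per-replicate VAF uses classified
reads only: ``n_mut / (n_mut + n_wt)``.

Reads that classify UNCLASSIFIED against every amplicon are still
attributed to an amplicon when exactly one amplicon's standalone flank
(the 15 bp immediately left or right of the edit) occurs in the read;
a single substitution inside the match window leaves at least one flank
intact, so such reads are counted as that amplicon's unclassified reads
rather than discarded. Reads matching nothing, or more than one amplicon,
land in the unassigned bucket. Total read count is conserved across all
buckets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .amplicon import AmpliconRef, TagSet

__all__ = [
    "WT", "MUT", "UNCLASSIFIED", "ReplicateCount", "DemuxResult",
    "classify_read", "demultiplex", "count_replicate", "quantify_reads",
    "revcomp",
]

WT = "WT"
MUT = "MUT"
UNCLASSIFIED = "UNCLASSIFIED"

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ReplicateCount:
    """Classified read tallies for one (marker, replicate).

    ``vaf`` is mutant over classified (``n_mut + n_wt``); it is undefined
    (None) when no read matched either template.
    """

    marker_id: str
    replicate: int
    n_wt: int
    n_mut: int
    n_unclassified: int = 0

    def __post_init__(self):
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if min(self.n_wt, self.n_mut, self.n_unclassified) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_wt + self.n_mut + self.n_unclassified

    @property
    def vaf(self) -> Optional[float]:
        denom = self.n_wt + self.n_mut
        if denom == 0:
            return None
        return self.n_mut / denom


def classify_read(read_body: str, amp: AmpliconRef,
                  min_flank: int = 15, check_rc: bool = True) -> str:
    """Classify a tag-stripped read against one amplicon's templates.

    WT iff the read contains the wild-type exact-match window (ref allele
    plus ``min_flank`` bases of perfect context each side) as a contiguous
    substring; MUT for the mutant window; UNCLASSIFIED otherwise or on
    ambiguity (both windows present). With ``check_rc`` the reverse
    complement of the read is tried as well. Pure function.
    """
    if min_flank > min(amp.left_flank_len, amp.right_flank_len):
        # windows were designed with the amplicon's own flank lengths;
        # asking for more context than was guaranteed is a config error
        if amp.variant_offset_wt < min_flank or (
                len(amp.wt_seq) - amp.variant_offset_wt
                - len(amp.ref_allele)) < min_flank:
            raise ValueError(
                f"amplicon {amp.marker_id} cannot supply {min_flank} bp flanks")
    lo = amp.variant_offset_wt - min_flank
    wt_win = amp.wt_seq[lo:amp.variant_offset_wt + len(amp.ref_allele) + min_flank]
    mut_win = amp.mut_seq[lo:amp.variant_offset_wt + len(amp.alt_allele) + min_flank]

    bodies = (read_body, revcomp(read_body)) if check_rc else (read_body,)
    is_wt = any(wt_win in b for b in bodies)
    is_mut = any(mut_win in b for b in bodies)
    if is_wt and not is_mut:
        return WT
    if is_mut and not is_wt:
        return MUT
    return UNCLASSIFIED


def _flank_probes(amp: AmpliconRef, min_flank: int) -> tuple[str, str]:
    off = amp.variant_offset_wt
    left = amp.wt_seq[off - min_flank:off]
    right = amp.wt_seq[off + len(amp.ref_allele):
                       off + len(amp.ref_allele) + min_flank]
    return left, right


@dataclass
class DemuxResult:
    """Per-(marker, replicate) read buckets plus the unassigned pool."""

    buckets: dict[tuple[str, int], list[tuple[str, str]]]  # (read, class)
    unassigned: list[str]
    n_input: int

    def check_conservation(self) -> bool:
        routed = sum(len(v) for v in self.buckets.values())
        return routed + len(self.unassigned) == self.n_input


def demultiplex(
    reads: Iterable[Union[str, tuple[str, str]]],
    tagset: TagSet,
    amplicons: Sequence[AmpliconRef],
    min_flank: int = 15,
    check_rc: bool = True,
) -> DemuxResult:
    """Split a read stream by replicate tag and amplicon.

    ``reads`` may be bare sequences or ``(name, sequence)`` pairs. The
    replicate is fixed by an exact match of the leading ``tag_len`` bases
    (checked on the as-is orientation only); the amplicon by template
    classification of the remaining body, with flank-probe attribution for
    near-miss reads (see module docstring).
    """
    ids = [a.marker_id for a in amplicons]
    if len(set(ids)) != len(ids):
        raise ValueError("amplicon marker_ids must be unique")
    templates = {(a.wt_seq, a.mut_seq) for a in amplicons}
    if len(templates) != len(amplicons):
        raise ValueError("amplicon template pairs must be pairwise distinct")
    tag_of = {tagset.tag(r): r for r in (1, 2, 3)}
    tlen = tagset.tag_len
    probes = {a.marker_id: _flank_probes(a, min_flank) for a in amplicons}

    buckets: dict[tuple[str, int], list[tuple[str, str]]] = {}
    unassigned: list[str] = []
    n_input = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        n_input += 1
        rep = tag_of.get(seq[:tlen])
        if rep is None:
            unassigned.append(seq)
            continue
        body = seq[tlen:]
        hits = [(a, classify_read(body, a, min_flank, check_rc))
                for a in amplicons]
        matched = [(a, c) for a, c in hits if c != UNCLASSIFIED]
        if len(matched) == 1:
            amp, cls = matched[0]
        elif len(matched) == 0:
            bodies = (body, revcomp(body)) if check_rc else (body,)
            near = [a for a in amplicons
                    if any(p in b for p in probes[a.marker_id]
                           for b in bodies)]
            if len(near) == 1:
                amp, cls = near[0], UNCLASSIFIED
            else:
                unassigned.append(seq)
                continue
        else:  # matches two amplicons' templates: ambiguous routing
            unassigned.append(seq)
            continue
        buckets.setdefault((amp.marker_id, rep), []).append((body, cls))
    return DemuxResult(buckets=buckets, unassigned=unassigned, n_input=n_input)


def count_replicate(
    read_stream: Iterable[str],
    amp: AmpliconRef,
    replicate: int,
    min_flank: int = 15,
    check_rc: bool = True,
) -> ReplicateCount:
    """Tally classifications for one demultiplexed (marker, replicate)."""
    n = {WT: 0, MUT: 0, UNCLASSIFIED: 0}
    for body in read_stream:
        n[classify_read(body, amp, min_flank, check_rc)] += 1
    return ReplicateCount(marker_id=amp.marker_id, replicate=replicate,
                          n_wt=n[WT], n_mut=n[MUT],
                          n_unclassified=n[UNCLASSIFIED])


def quantify_reads(
    reads: Iterable[Union[str, tuple[str, str]]],
    tagset: TagSet,
    amplicons: Sequence[AmpliconRef],
    min_flank: int = 15,
    check_rc: bool = True,
) -> tuple[list[ReplicateCount], DemuxResult]:
    """Demultiplex a FASTQ stream and produce per-replicate counts.

    Returns counts for every (marker, replicate) bucket that received at
    least one read, in (marker_id, replicate) order, plus the demultiplex
    result for conservation auditing.
    """
    demux = demultiplex(reads, tagset, amplicons, min_flank, check_rc)
    counts: list[ReplicateCount] = []
    for (marker_id, rep), items in sorted(demux.buckets.items()):
        n = {WT: 0, MUT: 0, UNCLASSIFIED: 0}
        for _body, cls in items:
            n[cls] += 1
        counts.append(ReplicateCount(
            marker_id=marker_id, replicate=rep,
            n_wt=n[WT], n_mut=n[MUT], n_unclassified=n[UNCLASSIFIED]))
    return counts, demux


def read_fastq(path) -> Iterable[tuple[str, str]]:
    """Stream (name, sequence) pairs from FASTQ or FASTQ.gz."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence
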