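"""Wild-type / mutant amplicon template design.

Each tracked variant gets a pair of template sequences against which reads
are later matched exactly: the wild-type context around the locus and the
same window with the ref→alt edit applied. Templates are capped at 140 bp
and the variant is placed as close to the window centre as the context
allows, with at least 15 bp of flanking reference sequence guaranteed on
each side.

Genomic inputs are 1-based inclusive; every internal offset is 0-based
half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .markers import MarkerVariant, deanchor

__all__ = [
    "AmpliconRef", "TagSet", "DesignError", "ReferenceMismatchError",
    "apply_edit", "design_amplicon", "load_contexts_fasta",
    "write_amplicons_json", "load_amplicons_json",
]

DEFAULT_MAX_LEN = 140
DEFAULT_MIN_FLANK = 15

_DNA = frozenset("ACGT")


class DesignError(ValueError):
    """The context cannot accommodate the size/flank constraints."""


class ReferenceMismatchError(ValueError):
    """The stated ref allele does not match the provided sequence."""


def apply_edit(wt_seq: str, variant_offset: int, ref_allele: str,
               alt_allele: str) -> str:
    """Replace ``ref_allele`` with ``alt_allele`` at a 0-based offset.

    Supports SNV, MNV, insertion (empty/short ref) and deletion (empty/short
    alt). Pure function.
    """
    end = variant_offset + len(ref_allele)
    if variant_offset < 0 or end > len(wt_seq):
        raise ReferenceMismatchError(
            f"edit window [{variant_offset}, {end}) outside sequence "
            f"of length {len(wt_seq)}")
    if wt_seq[variant_offset:end] != ref_allele:
        raise ReferenceMismatchError(
            f"expected {ref_allele!r} at offset {variant_offset}, "
            f"found {wt_seq[variant_offset:end]!r}")
    return wt_seq[:variant_offset] + alt_allele + wt_seq[end:]


@dataclass(frozen=True)
class AmpliconRef:
    """Paired WT/mutant templates for one marker.

    ``variant_offset_wt`` is the 0-based offset of the first affected base
    in ``wt_seq``; the same offset locates the alt allele in ``mut_seq``.
    """

    marker_id: str
    wt_seq: str
    mut_seq: str
    variant_offset_wt: int
    ref_allele: str
    alt_allele: str
    left_flank_len: int = DEFAULT_MIN_FLANK
    right_flank_len: int = DEFAULT_MIN_FLANK
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(self.wt_seq) > self.max_len:
            raise DesignError(
                f"wt_seq length {len(self.wt_seq)} exceeds cap {self.max_len}")
        if set(self.wt_seq) - _DNA or set(self.mut_seq) - _DNA:
            raise DesignError("templates must be uppercase ACGT")
        if self.variant_offset_wt < self.left_flank_len:
            raise DesignError(
                f"left flank {self.variant_offset_wt} < {self.left_flank_len}")
        right = (len(self.wt_seq) - self.variant_offset_wt
                 - len(self.ref_allele))
        if right < self.right_flank_len:
            raise DesignError(
                f"right flank {right} < {self.right_flank_len}")
        expected = apply_edit(self.wt_seq, self.variant_offset_wt,
                              self.ref_allele, self.alt_allele)
        if expected != self.mut_seq:
            raise DesignError("mut_seq is not wt_seq with the edit applied")

    @property
    def wt_window(self) -> str:
        """Exact-match window for WT classification: ref allele plus flanks."""
        lo = self.variant_offset_wt - self.left_flank_len
        hi = self.variant_offset_wt + len(self.ref_allele) + self.right_flank_len
        return self.wt_seq[lo:hi]

    @property
    def mut_window(self) -> str:
        """Exact-match window for MUT classification: alt allele plus flanks."""
        lo = self.variant_offset_wt - self.left_flank_len
        hi = self.variant_offset_wt + len(self.alt_allele) + self.right_flank_len
        return self.mut_seq[lo:hi]


@dataclass(frozen=True)
class TagSet:
    """The three replicate tags (P1, P2, P3) prepended to reads."""

    tags: tuple[str, str, str]

    def __post_init__(self):
        if len(self.tags) != 3:
            raise ValueError("exactly 3 replicate tags required")
        if len(set(self.tags)) != 3:
            raise ValueError("replicate tags must be pairwise distinct")
        lengths = {len(t) for t in self.tags}
        if len(lengths) != 1:
            raise ValueError("replicate tags must have equal length")
        for t in self.tags:
            if set(t) - _DNA:
                raise ValueError(f"tag {t!r} contains non-ACGT characters")

    @property
    def tag_len(self) -> int:
        return len(self.tags[0])

    def tag(self, replicate: int) -> str:
        """Tag for replicate 1, 2 or 3."""
        if replicate not in (1, 2, 3):
            raise ValueError(f"replicate must be 1..3, got {replicate}")
        return self.tags[replicate - 1]

    @classmethod
    def default(cls) -> "TagSet":
        return cls(("ACGTACGT", "CAGTCAGT", "GTCAGTCA"))


def design_amplicon(
    context_seq: str,
    context_start: int,
    variant: MarkerVariant,
    max_len: int = DEFAULT_MAX_LEN,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> AmpliconRef:
    """Choose the template window for a marker and build the WT/MUT pair.

    ``context_seq`` is reference sequence beginning at 1-based genomic
    position ``context_start``. The window has length
    ``min(max_len, len(context_seq))`` and is chosen to minimise the distance
    between the midpoint of the ref span and the window centre, subject to
    ``min_flank`` reference bases on each side of the edit; ties go to the
    smaller genomic start. Deterministic.
    """
    variant = deanchor(variant)
    context_seq = context_seq.upper()
    ref, alt = variant.ref_allele, variant.alt_allele
    ctx_off = variant.pos - context_start  # 0-based offset of first ref base
    if ctx_off < 0 or ctx_off + len(ref) > len(context_seq):
        raise DesignError(
            f"variant at pos {variant.pos} outside context "
            f"[{context_start}, {context_start + len(context_seq)})")
    if context_seq[ctx_off:ctx_off + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"context has {context_seq[ctx_off:ctx_off + len(ref)]!r} at "
            f"pos {variant.pos}, marker says {ref!r}")

    win_len = min(max_len, len(context_seq))
    # feasible starts: min_flank left of the edit and right of it, window
    # inside the context
    lo = max(0, ctx_off + len(ref) + min_flank - win_len)
    hi = min(len(context_seq) - win_len, ctx_off - min_flank)
    if lo > hi:
        raise DesignError(
            f"cannot fit {min_flank} bp flanks around a {len(ref)} bp ref "
            f"span in a {win_len} bp window of this context")
    # centring target: midpoint of the ref span vs midpoint of the window
    best = None
    for start in range(lo, hi + 1):
        offset = ctx_off - start
        dist = abs(offset - (win_len - len(ref)) / 2)
        if best is None or dist < best[0]:
            best = (dist, start)
    _, start = best
    wt_seq = context_seq[start:start + win_len]
    offset = ctx_off - start
    mut_seq = apply_edit(wt_seq, offset, ref, alt)
    return AmpliconRef(
        marker_id=variant.marker_id,
        wt_seq=wt_seq, mut_seq=mut_seq, variant_offset_wt=offset,
        ref_allele=ref, alt_allele=alt,
        left_flank_len=min_flank, right_flank_len=min_flank, max_len=max_len,
    )


# ---------------------------------------------------------------------------
# I/O

def load_contexts_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read marker locus contexts (one FASTA record per marker,
    ID = ``patient_id:gene:hgvs_p``)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_amplicons_json(amplicons: Sequence[AmpliconRef],
                         path: Union[str, Path]) -> None:
    payload = [{
        "marker_id": a.marker_id, "wt_seq": a.wt_seq, "mut_seq": a.mut_seq,
        "variant_offset_wt": a.variant_offset_wt,
        "ref_allele": a.ref_allele, "alt_allele": a.alt_allele,
        "left_flank_len": a.left_flank_len,
        "right_flank_len": a.right_flank_len, "max_len": a.max_len,
    } for a in amplicons]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_amplicons_json(path: Union[str, Path]) -> list[AmpliconRef]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [AmpliconRef(**entry) for entry in payload]
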