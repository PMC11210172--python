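"""The LiqBio-MRD statistical core.

From triplicate VAFs to a sample-level MRD call, in four steps:

1. **Triplicate noise filter** — within a marker's triplicate, replicates
   whose VAF strictly exceeds the triplicate's own mean + 1 sample SD are
   excluded (PCR jackpots); the marker VAF is the mean of the retained
   replicates.
2. **LOD calibration** — each marker's limit of detection is the mean + 3
   sample SDs of its nine healthy-control background points (3 donors x 3
   replicates run through the same pipeline).
3. **LOD gate** — a marker whose VAF is strictly below its LOD is excluded
   from the call (status ``below_lod``).
4. **MRD call** — the sample's MRD value is the highest surviving marker
   VAF; the sample is MRD-positive when that value reaches the 1e-4
   threshold (inclusive boundary).

Sample QC mirrors the assay's input requirements: at least 15 ng for
cfDNA, 660 ng for the cellular (gDNA) fraction, and a gDNA/cfDNA
contamination ratio no higher than one for cfDNA samples.

All VAFs are dimensionless fractions; sample standard deviations use the
k-1 denominator throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .quantify import ReplicateCount

__all__ = [
    "DEFAULT_THRESHOLD", "LODEntry", "MarkerMeasurement", "SampleQC",
    "MRDCall", "filter_triplicates", "compute_lod", "apply_lod",
    "call_mrd", "sample_qc", "measure_marker", "call_sample",
]

DEFAULT_THRESHOLD = 1e-4

DETECTED = "detected"
BELOW_LOD = "below_lod"
EXCLUDED_QC = "excluded_qc"
NO_DATA = "no_data"


@dataclass(frozen=True)
class LODEntry:
    """Per-marker limit of detection from the nine-point control background."""

    marker_id: str
    control_vafs: tuple[float, ...]
    lod: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.control_vafs))


def compute_lod(marker_id: str, control_vafs: Sequence[float],
                strict: bool = True, sd_multiplier: float = 3.0) -> LODEntry:
    """LOD = mean + 3 sample SDs of the control background VAFs.

    Strict mode (default) demands exactly nine points (three donors in
    triplicate); lenient mode accepts any n >= 2.
    """
    vals = [float(v) for v in control_vafs]
    if strict and len(vals) != 9:
        raise ValueError(
            f"{marker_id}: expected exactly 9 control points, got {len(vals)}")
    if len(vals) < 2:
        raise ValueError(f"{marker_id}: need >= 2 control points")
    if any(not 0 <= v <= 1 or not math.isfinite(v) for v in vals):
        raise ValueError(f"{marker_id}: control VAFs must be finite in [0,1]")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return LODEntry(marker_id=marker_id, control_vafs=tuple(vals),
                    lod=mean + sd_multiplier * sd)


@dataclass(frozen=True)
class MarkerMeasurement:
    """A marker's post-filter VAF in one sample, with provenance."""

    marker_id: str
    replicate_counts: tuple[ReplicateCount, ...]
    retained_replicates: tuple[int, ...]
    marker_vaf: Optional[float]
    lod: Optional[float] = None
    status: str = NO_DATA


def filter_triplicates(
    counts: Sequence[ReplicateCount],
    sd_multiplier: float = 1.0,
) -> MarkerMeasurement:
    """Exclude outlier replicates and average the rest.

    Replicates with undefined VAF are dropped first. With k >= 2 defined
    VAFs, any replicate whose VAF is strictly greater than their mean +
    ``sd_multiplier`` sample SDs (k-1 denominator) is excluded; the marker
    VAF is the mean of what remains. A lone defined replicate is retained
    as-is; no defined replicates means no data. Zero-variance triplicates
    are never pruned (strict inequality).
    """
    if len(counts) > 3:
        raise ValueError(f"at most 3 replicates expected, got {len(counts)}")
    ids = {c.marker_id for c in counts}
    if len(ids) > 1:
        raise ValueError(f"mixed markers in one triplicate: {sorted(ids)}")
    defined = [(c.replicate, c.vaf) for c in counts if c.vaf is not None]
    if not defined:
        return MarkerMeasurement(
            marker_id=counts[0].marker_id if counts else "",
            replicate_counts=tuple(counts), retained_replicates=(),
            marker_vaf=None, status=NO_DATA)
    if len(defined) == 1:
        rep, vaf = defined[0]
        return MarkerMeasurement(
            marker_id=counts[0].marker_id, replicate_counts=tuple(counts),
            retained_replicates=(rep,), marker_vaf=vaf, status=DETECTED)
    vafs = np.array([v for _, v in defined])
    cutoff = float(np.mean(vafs)) + sd_multiplier * float(np.std(vafs, ddof=1))
    retained = [(r, v) for r, v in defined if v <= cutoff]
    marker_vaf = float(np.mean([v for _, v in retained]))
    return MarkerMeasurement(
        marker_id=counts[0].marker_id, replicate_counts=tuple(counts),
        retained_replicates=tuple(r for r, _ in retained),
        marker_vaf=marker_vaf, status=DETECTED)


def apply_lod(measurement: MarkerMeasurement,
              lod_entry: Optional[LODEntry],
              missing_lod: str = "error") -> MarkerMeasurement:
    """Gate a measurement on its marker's LOD.

    Status becomes ``below_lod`` iff the marker VAF is strictly lower than
    the LOD (a VAF exactly at the LOD stays detected). ``missing_lod``:
    "error" (default) or "zero" (treat as LOD 0 and keep the marker).
    """
    from dataclasses import replace

    if lod_entry is None:
        if missing_lod == "error":
            raise ValueError(f"no LOD entry for marker {measurement.marker_id}")
        lod = 0.0
    else:
        if lod_entry.marker_id != measurement.marker_id:
            raise ValueError(
                f"LOD marker {lod_entry.marker_id!r} does not match "
                f"measurement {measurement.marker_id!r}")
        lod = lod_entry.lod
    if measurement.status == NO_DATA or measurement.marker_vaf is None:
        return replace(measurement, lod=lod)
    status = BELOW_LOD if measurement.marker_vaf < lod else DETECTED
    return replace(measurement, lod=lod, status=status)


@dataclass(frozen=True)
class SampleQC:
    """Input-material QC for one sample."""

    sample_id: str
    fraction: str  # "cfDNA" | "CTC"
    dna_ng: float
    gdna_cfdna_ratio: Optional[float] = None
    min_cfdna_ng: float = 15.0
    min_gdna_ng: float = 660.0
    max_gdna_ratio: float = 1.0

    def __post_init__(self):
        if self.fraction not in ("cfDNA", "CTC"):
            raise ValueError(f"fraction must be cfDNA or CTC, got {self.fraction!r}")
        if self.dna_ng < 0:
            raise ValueError("dna_ng must be non-negative")
        if self.gdna_cfdna_ratio is not None and self.gdna_cfdna_ratio < 0:
            raise ValueError("gdna_cfdna_ratio must be non-negative")

    @property
    def reasons(self) -> tuple[str, ...]:
        out = []
        minimum = (self.min_cfdna_ng if self.fraction == "cfDNA"
                   else self.min_gdna_ng)
        if self.dna_ng < minimum:
            out.append("low_input")
        if (self.fraction == "cfDNA" and self.gdna_cfdna_ratio is not None
                and self.gdna_cfdna_ratio > self.max_gdna_ratio):
            out.append("high_gdna_ratio")
        return tuple(out)

    @property
    def passed(self) -> bool:
        return not self.reasons


def sample_qc(sample_id: str, fraction: str, dna_ng: float,
              gdna_cfdna_ratio: Optional[float] = None, **limits) -> SampleQC:
    """Evaluate a sample's input-material QC; see :class:`SampleQC`."""
    return SampleQC(sample_id=sample_id, fraction=fraction, dna_ng=dna_ng,
                    gdna_cfdna_ratio=gdna_cfdna_ratio, **limits)


@dataclass(frozen=True)
class MRDCall:
    """Sample-level MRD: the highest surviving marker VAF vs the threshold."""

    sample_id: str
    fraction: str
    best_marker: Optional[str]
    mrd_value: float
    positive: bool
    threshold: float = DEFAULT_THRESHOLD
    provenance: tuple[MarkerMeasurement, ...] = ()
    warnings: tuple[str, ...] = ()


def call_mrd(
    measurements: Sequence[MarkerMeasurement],
    threshold: float = DEFAULT_THRESHOLD,
    sample_id: str = "sample",
    fraction: str = "cfDNA",
) -> MRDCall:
    """The final call: MRD value = max marker VAF over detected markers.

    Positive iff that value is >= threshold (inclusive). Markers below
    their LOD or without data do not contribute. Ties on the maximum are
    broken by lexicographic marker_id. An empty measurement list yields a
    negative call flagged with a warning.
    """
    warnings = ()
    if not measurements:
        warnings = ("no_measurements",)
    measurements = sorted(measurements, key=lambda m: m.marker_id)
    detected = [m for m in measurements
                if m.status == DETECTED and m.marker_vaf is not None]
    if not detected:
        return MRDCall(sample_id=sample_id, fraction=fraction,
                       best_marker=None, mrd_value=0.0, positive=False,
                       threshold=threshold, provenance=tuple(measurements),
                       warnings=warnings)
    mrd_value = max(m.marker_vaf for m in detected)
    best = min((m for m in detected if m.marker_vaf == mrd_value),
               key=lambda m: m.marker_id)
    return MRDCall(sample_id=sample_id, fraction=fraction,
                   best_marker=best.marker_id, mrd_value=mrd_value,
                   positive=mrd_value >= threshold, threshold=threshold,
                   provenance=tuple(measurements), warnings=warnings)


# ---------------------------------------------------------------------------
# Convenience composition

def measure_marker(counts: Sequence[ReplicateCount],
                   lod_entry: Optional[LODEntry],
                   sd_multiplier: float = 1.0,
                   missing_lod: str = "error") -> MarkerMeasurement:
    """filter_triplicates then apply_lod for one marker's triplicate."""
    return apply_lod(filter_triplicates(counts, sd_multiplier), lod_entry,
                     missing_lod)


def call_sample(
    counts_by_marker: dict[str, Sequence[ReplicateCount]],
    lods: dict[str, LODEntry],
    threshold: float = DEFAULT_THRESHOLD,
    sample_id: str = "sample",
    fraction: str = "cfDNA",
    qc: Optional[SampleQC] = None,
    sd_multiplier: float = 1.0,
    missing_lod: str = "error",
) -> MRDCall:
    """Run the full marker-to-call chain for one sample.

    A sample failing QC is returned as a negative call with every marker
    marked ``excluded_qc`` and a qc warning, mirroring the exclusion of
    under-input samples from analysis.
    """
    from dataclasses import replace

    if qc is not None and not qc.passed:
        meas = tuple(
            replace(filter_triplicates(c, sd_multiplier), status=EXCLUDED_QC)
            for c in counts_by_marker.values())
        return MRDCall(sample_id=sample_id, fraction=fraction,
                       best_marker=None, mrd_value=0.0, positive=False,
                       threshold=threshold, provenance=meas,
                       warnings=tuple(f"qc_fail:{r}" for r in qc.reasons))
    measurements = [
        measure_marker(c, lods.get(mid), sd_multiplier, missing_lod)
        for mid, c in sorted(counts_by_marker.items())
    ]
    return call_mrd(measurements, threshold, sample_id, fraction)
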