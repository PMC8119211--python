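"""Size-profile statistics for cfDNA fragmentomics.

Implements the profile-level quantities used to compare cfDNA samples:

* cumulative size-frequency curves S(x);
* ΔS (difference of cumulative frequencies, percent) and ΔV (per-length
  difference of frequencies, percent) between two profiles;
* range fractions (e.g. the <90 / 90–240 / 241–440 bp partition of the
  mono-/di-nucleosome window), the 166/145 frequency ratio, and the modal
  peak;
* ~10 bp sub-peak detection, periodicity, and the SSP-vs-DSP sub-peak
  stagger offset;
* per-sample feature panels against a healthy reference profile and
  Spearman trends of those features against the mutant allele fraction
  (MAF) of the sample.

ΔS and ΔV are expressed in percent; both operand profiles are renormalized
over the common support before differencing, so ΔS vanishes at the upper end
of the common support and ΔS is the running sum of ΔV.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .io import SizeProfile

__all__ = [
    "CumulativeCurve",
    "DeltaCurve",
    "SubpeakReport",
    "FeaturePanel",
    "MafTrend",
    "cumulative",
    "delta_s",
    "delta_v",
    "range_fraction",
    "peak",
    "detect_subpeaks",
    "periodicity",
    "stagger_offset",
    "ratio_at",
    "reference_mean",
    "feature_panel",
    "maf_trend",
    "RANGE_BOUNDS",
    "SUBPEAK_SMOOTH_HALFWIDTH",
    "SUBPEAK_MIN_PROMINENCE",
]

#: The three-range partition of the 30–440 bp mono-/di-nucleosome window:
#: sub-mono (<90), mono (90–240) and di-nucleosome (241–440) ranges.
RANGE_BOUNDS = ((30, 89), (90, 240), (241, 440))

#: Default sub-peak smoothing half-width (5-bp centered moving average) and
#: prominence factor relative to the median in-window frequency.  Chosen so a
#: 10-bp comb is resolved while single-bp noise is not.
SUBPEAK_SMOOTH_HALFWIDTH = 2
SUBPEAK_MIN_PROMINENCE = 0.15


@dataclass
class CumulativeCurve:
    """Cumulative size-frequency curve S(x) of a profile."""

    assay: str
    support: tuple[int, int]
    values: np.ndarray  # S at each length of the support, nondecreasing

    @property
    def lengths(self) -> np.ndarray:
        lo, hi = self.support
        return np.arange(lo, hi + 1, dtype=np.int64)

    def at(self, length: int) -> float:
        lo, hi = self.support
        if length < lo:
            return 0.0
        if length > hi:
            return 1.0
        return float(self.values[length - lo])


@dataclass
class DeltaCurve:
    """ΔS or ΔV curve between two profiles, in signed percent."""

    kind: str  # "DELTA_S" | "DELTA_V"
    support: tuple[int, int]
    values: np.ndarray
    operands: tuple[str, str]

    @property
    def lengths(self) -> np.ndarray:
        lo, hi = self.support
        return np.arange(lo, hi + 1, dtype=np.int64)

    def at(self, length: int) -> float:
        lo, hi = self.support
        if not lo <= length <= hi:
            raise ValueError(f"length {length} outside support {self.support}")
        return float(self.values[length - lo])

    def sum_over(self, lo: int, hi: int) -> float:
        """Sum of per-length values over [lo, hi] inclusive (clipped)."""
        slo, shi = self.support
        lo, hi = max(lo, slo), min(hi, shi)
        if lo > hi:
            return 0.0
        return float(self.values[lo - slo : hi - slo + 1].sum())


@dataclass
class SubpeakReport:
    """Detected sub-peak positions within a search window."""

    positions: list[int]
    search_window: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.search_window
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("sub-peak positions must be strictly increasing")
        if self.positions and not (lo <= self.positions[0] and self.positions[-1] <= hi):
            raise ValueError("sub-peak positions must lie inside the search window")

    @property
    def spacings(self) -> list[int]:
        return [b - a for a, b in zip(self.positions, self.positions[1:])]

    @property
    def summary_spacing(self) -> int:
        return periodicity(self)


@dataclass
class FeaturePanel:
    """Discriminatory fragmentomic statistics for one sample.

    Delta fields are measured against a healthy reference profile and are
    ``None`` when no reference was supplied.  ``range_pcts`` partitions the
    30–440 bp window and sums to 100.
    """

    assay: str
    peak_position: int
    peak_height_pct: float
    ratio_166_145: float
    frac_short_pct: float
    range_pcts: dict[tuple[int, int], float]
    dinucleosome_peak: int
    delta_s_at_155: float | None = None
    delta_v_40_160: float | None = None
    dii: float | None = None
    maf_pct: float | None = None

    def as_dict(self) -> dict:
        d = {
            "assay": self.assay,
            "peak_position": self.peak_position,
            "peak_height_pct": self.peak_height_pct,
            "ratio_166_145": self.ratio_166_145,
            "frac_short_pct": self.frac_short_pct,
            "dinucleosome_peak": self.dinucleosome_peak,
            "delta_s_at_155": self.delta_s_at_155,
            "delta_v_40_160": self.delta_v_40_160,
            "dii": self.dii,
            "maf_pct": self.maf_pct,
        }
        for (lo, hi), pct in self.range_pcts.items():
            d[f"pct_{lo}_{hi}"] = pct
        return d


@dataclass
class MafTrend:
    """Spearman rank correlations of panel features against MAF.

    ``correlations`` maps feature name -> Spearman rho; a feature constant
    across samples has correlation ``nan`` (undefined, not zero).
    """

    correlations: dict[str, float]
    n_samples: int
    mafs: list[float] = field(default_factory=list)


def cumulative(profile: SizeProfile) -> CumulativeCurve:
    """Cumulative curve S(x) = sum of frequencies at lengths <= x."""
    return CumulativeCurve(
        assay=profile.assay,
        support=profile.support,
        values=np.cumsum(profile.freqs),
    )


def _common_support(a: SizeProfile, b: SizeProfile) -> tuple[int, int]:
    lo = max(a.support[0], b.support[0])
    hi = min(a.support[1], b.support[1])
    if lo > hi:
        raise ValueError(
            f"profiles have disjoint supports {a.support} and {b.support}"
        )
    return lo, hi


def delta_s(a: SizeProfile, b: SizeProfile) -> DeltaCurve:
    """ΔS(x) = 100·(S_a(x) − S_b(x)) on the common support.

    Positive where ``a`` accumulates frequency faster, i.e. holds more short
    fragments.  Both profiles are renormalized over the common support, so
    ΔS at the upper end is exactly zero.
    """
    lo, hi = _common_support(a, b)
    fa = a.renormalized(lo, hi).freqs
    fb = b.renormalized(lo, hi).freqs
    values = 100.0 * (np.cumsum(fa) - np.cumsum(fb))
    return DeltaCurve(
        kind="DELTA_S", support=(lo, hi), values=values, operands=(a.assay, b.assay)
    )


def delta_v(a: SizeProfile, b: SizeProfile) -> DeltaCurve:
    """ΔV(x) = 100·(f_a(x) − f_b(x)) on the common support (renormalized)."""
    lo, hi = _common_support(a, b)
    fa = a.renormalized(lo, hi).freqs
    fb = b.renormalized(lo, hi).freqs
    return DeltaCurve(
        kind="DELTA_V",
        support=(lo, hi),
        values=100.0 * (fa - fb),
        operands=(a.assay, b.assay),
    )


def range_fraction(
    profile: SizeProfile,
    lo: int,
    hi: int,
    denom_lo: int | None = None,
    denom_hi: int | None = None,
) -> float:
    """Percent of denominator-window mass lying in [lo, hi] inclusive.

    The denominator defaults to the full support.  Ranges are closed on both
    integer endpoints, so the partition (30–89, 90–240, 241–440) covers
    30–440 without overlap.
    """
    slo, shi = profile.support
    if denom_lo is None:
        denom_lo = slo
    if denom_hi is None:
        denom_hi = shi
    if not (denom_lo <= lo and hi <= denom_hi):
        raise ValueError(
            f"range [{lo},{hi}] must lie within denominator [{denom_lo},{denom_hi}]"
        )
    denom = profile.freqs[max(denom_lo, slo) - slo : min(denom_hi, shi) - slo + 1].sum()
    if denom <= 0:
        raise ZeroDivisionError(
            f"no frequency mass in denominator range [{denom_lo},{denom_hi}]"
        )
    lo_c, hi_c = max(lo, slo), min(hi, shi)
    num = profile.freqs[lo_c - slo : hi_c - slo + 1].sum() if lo_c <= hi_c else 0.0
    return float(100.0 * num / denom)


def peak(profile: SizeProfile, window: tuple[int, int]) -> tuple[int, float]:
    """(position, height in percent) of the frequency maximum in the window.

    Ties break to the smallest length.
    """
    slo, shi = profile.support
    lo, hi = max(window[0], slo), min(window[1], shi)
    if lo > hi:
        raise ValueError(f"window {window} does not overlap support {profile.support}")
    sub = profile.freqs[lo - slo : hi - slo + 1]
    idx = int(np.argmax(sub))  # argmax returns the first (smallest-length) maximum
    return lo + idx, float(100.0 * sub[idx])


def detect_subpeaks(
    profile: SizeProfile,
    window: tuple[int, int],
    smooth_halfwidth: int = SUBPEAK_SMOOTH_HALFWIDTH,
    min_prominence: float = SUBPEAK_MIN_PROMINENCE,
) -> SubpeakReport:
    """Detect ~periodic sub-peaks of the profile within a window.

    The frequency is smoothed by a centered moving average of width
    ``2*smooth_halfwidth + 1``; local maxima of the smoothed signal with
    prominence >= ``min_prominence * median(in-window frequency)`` are kept,
    and each is reported at the unsmoothed argmax within ±halfwidth of the
    smoothed maximum.
    """
    slo, shi = profile.support
    lo, hi = max(window[0], slo), min(window[1], shi)
    width = 2 * smooth_halfwidth + 1
    if hi - lo + 1 < width:
        raise ValueError(
            f"window [{lo},{hi}] shorter than smoothing kernel ({width} bp)"
        )
    raw = profile.freqs[lo - slo : hi - slo + 1]
    kernel = np.ones(width) / width
    # Truncated-kernel edges: divide by the actual number of averaged points.
    smoothed = np.convolve(raw, kernel, mode="same")
    norm = np.convolve(np.ones_like(raw), kernel, mode="same")
    smoothed = smoothed / norm
    threshold = min_prominence * float(np.median(raw))
    peaks, _ = signal.find_peaks(smoothed, prominence=max(threshold, 1e-300))
    positions: dict[int, float] = {}
    for p in peaks:
        a = max(0, p - smooth_halfwidth)
        b = min(len(raw), p + smooth_halfwidth + 1)
        local = int(np.argmax(raw[a:b])) + a
        pos = int(lo + local)
        height = float(raw[local])
        if pos not in positions or height > positions[pos]:
            positions[pos] = height
    return SubpeakReport(positions=sorted(positions), search_window=(lo, hi))


def periodicity(report: SubpeakReport) -> int:
    """Median sub-peak spacing in bp, rounded to the nearest integer.

    A half-integer median rounds down (e.g. 10.5 -> 10).
    """
    if len(report.positions) < 3:
        raise ValueError(
            f"periodicity needs >= 3 sub-peaks, got {len(report.positions)}"
        )
    med = float(np.median(report.spacings))
    return int(math.ceil(med - 0.5))  # round half down


def stagger_offset(a: SubpeakReport, b: SubpeakReport) -> int:
    """Modal signed offset (bp) from each sub-peak of ``a`` to its nearest
    sub-peak in ``b``.

    Ties between equally frequent offsets break to the smallest absolute
    value.
    """
    if len(a.positions) < 2 or len(b.positions) < 2:
        raise ValueError("stagger_offset needs >= 2 sub-peaks in each report")
    b_arr = np.asarray(b.positions)
    diffs = []
    for pos in a.positions:
        nearest = b_arr[np.argmin(np.abs(b_arr - pos))]
        diffs.append(int(pos - nearest))
    counts = Counter(diffs)
    best = sorted(counts.items(), key=lambda kv: (-kv[1], abs(kv[0]), kv[0]))
    return best[0][0]


def ratio_at(profile: SizeProfile, num_len: int = 166, den_len: int = 145) -> float:
    """Frequency ratio f(num_len) / f(den_len), e.g. the 166/145 ratio."""
    den = profile.frequency(den_len)
    if den <= 0:
        raise ZeroDivisionError(
            f"zero frequency at denominator length {den_len} bp"
        )
    return profile.frequency(num_len) / den


def reference_mean(profiles: Sequence[SizeProfile]) -> SizeProfile:
    """Mean profile of a cohort: per-length arithmetic mean of frequencies on
    the union support, renormalized; used as the healthy reference."""
    if not profiles:
        raise ValueError("reference_mean needs at least one profile")
    assays = {p.assay for p in profiles}
    if len(assays) > 1:
        raise ValueError(f"mixed assay labels in reference cohort: {sorted(assays)}")
    lo = min(p.support[0] for p in profiles)
    hi = max(p.support[1] for p in profiles)
    acc = np.zeros(hi - lo + 1)
    for p in profiles:
        plo, phi = p.support
        acc[plo - lo : phi - lo + 1] += p.freqs
    acc /= len(profiles)
    acc /= acc.sum()
    return SizeProfile(
        assay=profiles[0].assay,
        support=(lo, hi),
        freqs=acc,
        n_fragments=sum(p.n_fragments for p in profiles),
    )


def feature_panel(
    dsp: SizeProfile,
    ssp: SizeProfile | None = None,
    reference: SizeProfile | None = None,
    dii: float | None = None,
    maf_pct: float | None = None,
    mono_window: tuple[int, int] = (80, 260),
    dinuc_window: tuple[int, int] = (270, 440),
) -> FeaturePanel:
    """Assemble the discriminatory feature panel for one sample.

    ``delta_s_at_155`` and ``delta_v_40_160`` are sample-minus-reference when
    a reference profile is given; with no reference but both assays present,
    ``delta_v_40_160`` falls back to the SSP-minus-DSP contrast.
    """
    pos, height = peak(dsp, mono_window)
    try:
        ratio = ratio_at(dsp, 166, 145)
    except ZeroDivisionError:
        ratio = math.inf if dsp.frequency(166) > 0 else math.nan
    frac_short = range_fraction(dsp, 30, 145, 30, 440)
    range_pcts = {
        (lo, hi): range_fraction(dsp, lo, hi, 30, 440) for lo, hi in RANGE_BOUNDS
    }
    dinuc_pos, _ = peak(dsp, dinuc_window)
    ds155 = dv = None
    if reference is not None:
        ds_curve = delta_s(dsp, reference)
        ds155 = ds_curve.at(155)
        dv = delta_v(dsp, reference).sum_over(40, 160)
    elif ssp is not None:
        dv = delta_v(ssp, dsp).sum_over(40, 160)
    return FeaturePanel(
        assay=dsp.assay,
        peak_position=pos,
        peak_height_pct=height,
        ratio_166_145=ratio,
        frac_short_pct=frac_short,
        range_pcts=range_pcts,
        dinucleosome_peak=dinuc_pos,
        delta_s_at_155=ds155,
        delta_v_40_160=dv,
        dii=dii,
        maf_pct=maf_pct,
    )


_TREND_FEATURES = (
    "frac_short_pct",
    "ratio_166_145",
    "peak_height_pct",
    "delta_s_at_155",
    "delta_v_40_160",
    "dii",
)


def maf_trend(panels: Sequence[FeaturePanel], mafs: Sequence[float]) -> MafTrend:
    """Spearman rank correlation of each panel feature against MAF.

    Features missing in any panel are skipped; a feature constant across the
    cohort is reported as ``nan`` (undefined), never as zero.
    """
    if len(panels) != len(mafs):
        raise ValueError("panels and mafs must have equal length")
    if len(panels) < 3:
        raise ValueError("maf_trend needs at least 3 samples")
    maf_arr = np.asarray(mafs, dtype=float)
    corrs: dict[str, float] = {}
    for name in _TREND_FEATURES:
        values = [getattr(p, name) for p in panels]
        if any(v is None for v in values):
            continue
        arr = np.asarray(values, dtype=float)
        if np.all(arr == arr[0]):
            corrs[name] = math.nan
            continue
        rho = stats.spearmanr(arr, maf_arr).statistic
        corrs[name] = float(rho)
    return MafTrend(correlations=corrs, n_samples=len(panels), mafs=list(map(float, mafs)))
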