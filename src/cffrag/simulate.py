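"""Mechanistic cfDNA fragment simulator under nucleosome protection.

The generative model emulates how nuclear chromatin released into plasma is
degraded by blood nucleases while histones protect the wrapped DNA:

* Molecules come in structural classes: the chromatosome (core + linker
  histone H1, ~166 bp, the modal detected length), the nucleosome core
  particle (147–160 bp after linker trimming), sub-nucleosomal trimmed
  fragments (166 minus multiples of the ~10.2 bp helical repeat),
  di-nucleosomes (~332 bp), traces of tri-nucleosomes, and high-molecular-
  weight chromatin (>1000 bp) that escapes sequencing but not Q-PCR.
* Nicks (single-strand breaks) occur independently per strand at the ~14
  minor-groove sites per nucleosome wrap where DNA faces away from the
  histone surface, every ~10.2 bp from each protected end.
* Opposing nicks in the same vicinity form a double-strand break.  A
  double-strand library (DSP) recovers a duplex segment only when at least
  one of its strands is nick-free; duplex segments shorter than a full
  nucleosome turn (70 bp) usually peel off and degrade.  A single-strand
  library (SSP) recovers the n+1 single-strand pieces released from n nicks
  on each strand, down to ~25 nt.
* The two strand paths on the nucleosome surface are cleaved with a 3 nt
  3' stagger, so single-strand pieces read ~3 nt longer than the blunted
  duplex fragments cut at the same sites; the simulator applies the
  stagger as a +3 nt reporting offset on every nick-bounded single-strand
  piece, which reproduces the observable SSP-above-DSP sub-peak shift.
* A malignant molecule population (shorter, more heavily trimmed, with a
  di-nucleosome shoulder near 300 bp and almost no high-molecular-weight
  chromatin) is mixed in with probability MAF/100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io import FragmentSet
from .qpcr import AmpliconPanel, DEFAULT_PANEL, QpcrResult, insilico_qpcr

__all__ = [
    "NucleosomeModel",
    "Molecule",
    "MoleculeSet",
    "CohortParams",
    "SampleResult",
    "DEFAULT_MODEL",
    "CLASSES",
    "simulate_molecules",
    "dsp_readout",
    "ssp_readout",
    "simulate_cohort",
    "malignant_mixture",
    "get_preset",
    "PRESETS",
]

CLASSES = ("CHROMATOSOME", "CORE", "SUBNUC", "DINUC", "TRINUC", "HIGH_MW")
_CLASS_INDEX = {name: i for i, name in enumerate(CLASSES)}
_HIGH_MW = _CLASS_INDEX["HIGH_MW"]
SOURCES = ("HEALTHY_LIKE", "MALIGNANT")

# Column layout of the site matrix: left-anchored sites, then right-anchored
# sites, then free (uniform) positions used only for high-MW molecules.
_MAX_PER_SIDE = 24
_N_COLS = 2 * _MAX_PER_SIDE


@dataclass(frozen=True)
class NucleosomeModel:
    """Structural constants and readout rules of the protection model.

    Lengths in bp (duplex) or nt (single strand).  ``peel_discard_prob`` is
    the probability that a duplex segment shorter than one full nucleosome
    turn peels off the histone surface and is degraded before sequencing.
    """

    core_len: int = 147
    chromatosome_len: int = 166
    n_groove_sites: int = 14
    site_spacing: float = 10.2
    stagger: int = 3
    full_turn: int = 70
    linker: int = 20
    ssp_min_len: int = 25
    ssp_reliable: int = 45
    dsp_min_len: int = 30
    wgs_max_len: int = 1000
    vicinity: int = 5
    peel_discard_prob: float = 0.9
    dsp_peel_len: int = 90
    ssp_short_survival: float = 0.05
    ssp_survival_full_len: int = 120
    ssp_end_smear: float = 1.5
    ssp_long_onset: int = 200
    ssp_long_decay: float = 95.0
    site_jitter: int = 1

    def __post_init__(self) -> None:
        for name in (
            "core_len", "chromatosome_len", "n_groove_sites", "full_turn",
            "linker", "ssp_min_len", "dsp_min_len", "wgs_max_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.peel_discard_prob <= 1.0:
            raise ValueError("peel_discard_prob must be in [0, 1]")

    def ssp_detect(self, lengths: np.ndarray) -> np.ndarray:
        """Sequencing detection ramp for single-strand pieces: 0 at the
        ~25 nt limit, rising linearly to 1 at the reliable-read length."""
        lengths = np.asarray(lengths, dtype=float)
        if self.ssp_reliable <= self.ssp_min_len:
            return (lengths >= self.ssp_min_len).astype(float)
        return np.clip(
            (lengths - self.ssp_min_len) / (self.ssp_reliable - self.ssp_min_len),
            0.0,
            1.0,
        )

    def ssp_survival(self, lengths: np.ndarray) -> np.ndarray:
        """Peel-off survival of nick-released single-strand pieces.

        A released piece stays protected in proportion to how much of the
        histone surface it still wraps: survival rises from
        ``ssp_short_survival`` below one full turn to 1 at
        ``ssp_survival_full_len`` nt.  Intact full-length strands of an
        uncut terminus-to-terminus molecule are not subject to it.
        """
        lengths = np.asarray(lengths, dtype=float)
        lo, hi = self.full_turn, self.ssp_survival_full_len
        if hi <= lo:
            return np.ones_like(lengths)
        return self.ssp_short_survival + (1.0 - self.ssp_short_survival) * np.clip(
            (lengths - lo) / (hi - lo), 0.0, 1.0
        )

    def ssp_capture(self, lengths: np.ndarray) -> np.ndarray:
        """Library-conversion efficiency of single-strand templates.

        Single-strand library preparation favours short templates; capture
        decays exponentially beyond ``ssp_long_onset`` nt with scale
        ``ssp_long_decay``.  A non-positive decay disables the effect.
        """
        lengths = np.asarray(lengths, dtype=float)
        if self.ssp_long_decay <= 0:
            return np.ones_like(lengths)
        return np.exp(-np.clip(lengths - self.ssp_long_onset, 0.0, None) / self.ssp_long_decay)


DEFAULT_MODEL = NucleosomeModel()


@dataclass(frozen=True)
class Molecule:
    """One double-stranded cfDNA molecule with per-strand nick positions."""

    ds_len: int
    watson_nicks: tuple[int, ...] = ()
    crick_nicks: tuple[int, ...] = ()
    origin: str = "CHROMATOSOME"
    source: str = "HEALTHY_LIKE"

    def __post_init__(self) -> None:
        if self.ds_len < 1:
            raise ValueError("ds_len must be >= 1")
        for nicks in (self.watson_nicks, self.crick_nicks):
            if any(not 0 < p < self.ds_len for p in nicks):
                raise ValueError("nick positions must lie strictly inside the molecule")
            if list(nicks) != sorted(nicks):
                raise ValueError("nick positions must be sorted")
        if self.origin not in CLASSES:
            raise ValueError(f"unknown origin class {self.origin!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


class MoleculeSet:
    """Vectorized container of simulated molecules.

    ``pos`` holds candidate nick coordinates (one column per minor-groove
    site), ``watson``/``crick`` mark which of them are nicked on each strand,
    and ``valid`` masks the columns that exist for each molecule.
    """

    def __init__(
        self,
        ds_len: np.ndarray,
        pos: np.ndarray,
        valid: np.ndarray,
        watson: np.ndarray,
        crick: np.ndarray,
        origin: np.ndarray,
        source: np.ndarray,
    ) -> None:
        self.ds_len = np.asarray(ds_len, dtype=np.int32)
        self.pos = np.asarray(pos, dtype=np.int32)
        self.valid = np.asarray(valid, dtype=bool)
        self.watson = np.asarray(watson, dtype=bool) & self.valid
        self.crick = np.asarray(crick, dtype=bool) & self.valid
        self.origin = np.asarray(origin, dtype=np.int8)
        self.source = np.asarray(source, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.ds_len)

    def __iter__(self) -> Iterator[Molecule]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Molecule:
        v = self.valid[i]
        return Molecule(
            ds_len=int(self.ds_len[i]),
            watson_nicks=tuple(sorted(int(p) for p in self.pos[i][v & self.watson[i]])),
            crick_nicks=tuple(sorted(int(p) for p in self.pos[i][v & self.crick[i]])),
            origin=CLASSES[self.origin[i]],
            source=SOURCES[self.source[i]],
        )

    def select(self, mask: np.ndarray) -> "MoleculeSet":
        return MoleculeSet(
            self.ds_len[mask], self.pos[mask], self.valid[mask],
            self.watson[mask], self.crick[mask], self.origin[mask], self.source[mask],
        )

    @property
    def n_nicks(self) -> np.ndarray:
        """Total nick count per molecule (both strands)."""
        return self.watson.sum(axis=1) + self.crick.sum(axis=1)

    def max_clean_runs(self) -> np.ndarray:
        """Per molecule, the longest nick-free run over both strands (bp)."""
        best = np.zeros(len(self), dtype=np.int32)
        for strand in (self.watson, self.crick):
            runs = _strand_pieces(self.ds_len, self.pos, strand)[0]
            best = np.maximum(best, runs.max(axis=1).astype(np.int32))
        return best


def _strand_pieces(
    ds_len: np.ndarray, pos: np.ndarray, nicked: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Single-strand runs between nicks (and molecule ends).

    Returns (pieces, piece_mask): ``pieces`` has shape (n, n_cols + 1);
    entries where ``piece_mask`` is False are padding.
    """
    n = len(ds_len)
    ends = ds_len[:, None]
    coords = np.where(nicked, pos, ends).astype(np.int32)
    coords.sort(axis=1)
    bounds = np.concatenate(
        [np.zeros((n, 1), np.int32), coords, ends.astype(np.int32)], axis=1
    )
    pieces = np.diff(bounds, axis=1)
    return pieces, pieces > 0


def _count_nicks_in_segments(
    bounds: np.ndarray, pos: np.ndarray, nick_mask: np.ndarray, chunk: int = 20000
) -> np.ndarray:
    """Count nicks strictly inside each segment (a, b) of ``bounds``.

    ``bounds`` has shape (n, m+1) defining m segments per molecule; returns
    (n, m) counts.  Row-chunked to bound peak memory.
    """
    n, m1 = bounds.shape
    out = np.empty((n, m1 - 1), dtype=np.int16)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        p = pos[sl][:, None, :]  # (c, 1, k)
        mask = nick_mask[sl][:, None, :]
        a = bounds[sl][:, :-1, None]  # (c, m, 1)
        b = bounds[sl][:, 1:, None]
        inside = mask & (p > a) & (p < b)
        out[sl] = inside.sum(axis=2)
    return out


# ---------------------------------------------------------------------------
# Cohort parameters and presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Mixture weights and nicking intensities for one cohort.

    ``weights`` are the structural-class proportions of the healthy-like
    component; ``maf_pct`` is the mutant allele fraction, used directly as
    the mixture weight of the frozen malignant component.  Per-sample
    heterogeneity is introduced by jittering the class weights on the
    log-odds scale with SD ``jitter_sd``.
    """

    weights: tuple[float, ...]  # in CLASSES order
    chromo_peak_mass: float = 0.10
    chromo_tail_left: float = 8.0
    chromo_tail_right: float = 28.0
    subnuc_decay: float = 0.45
    subnuc_jitter: int = 2
    dinuc_center: float = 332.0
    dinuc_sd: float = 12.0
    p_site_nick: float = 0.21
    protected_factor: float = 0.12
    dinuc_nick_factor: float = 1.0
    trinuc_nick_factor: float = 1.0
    hmw_nick_rate: float = 1e-3
    maf_pct: float = 0.0
    jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(CLASSES),):
            raise ValueError(f"weights must have {len(CLASSES)} entries (order {CLASSES})")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("class weights must be >= 0 and sum to 1")
        if not 0.0 <= self.maf_pct <= 100.0:
            raise ValueError("maf_pct must lie in [0, 100]")
        if not 0.0 <= self.p_site_nick <= 1.0:
            raise ValueError("p_site_nick must lie in [0, 1]")
        if not 0.0 < self.subnuc_decay < 1.0:
            raise ValueError("subnuc_decay must lie in (0, 1)")

    def weights_dict(self) -> dict[str, float]:
        return dict(zip(CLASSES, self.weights))


# Calibrated cohort presets.  The numeric values below were fixed once by a
# grid-refinement script (scripts/calibrate_presets.py) so that simulated
# cohorts pushed through the DSP/SSP/Q-PCR readouts reproduce published
# healthy- and cancer-plasma summary statistics; they are frozen constants,
# not free parameters.  See docs/methods.md.
_HEALTHY_CHROMATIN = {
    "CHROMATOSOME": 0.6314,
    "CORE": 0.2608,
    "SUBNUC": 0.0,
    "DINUC": 0.1078,
    "TRINUC": 0.0,
}


def _weights_tuple(d: dict[str, float]) -> tuple[float, ...]:
    w = np.array([d[c] for c in CLASSES], dtype=float)
    return tuple(w / w.sum())


def _with_hmw(chromatin: dict[str, float], hmw: float) -> dict[str, float]:
    total = sum(chromatin.values())
    d = {k: v * (1.0 - hmw) / total for k, v in chromatin.items()}
    d["HIGH_MW"] = hmw
    return d


_HEALTHY_BASE = dict(
    chromo_peak_mass=0.16,
    chromo_tail_left=35.0,
    chromo_tail_right=28.0,
    subnuc_decay=0.40,
    subnuc_jitter=2,
    dinuc_center=332.0,
    dinuc_sd=12.0,
    p_site_nick=0.2116,
    protected_factor=0.12,
    dinuc_nick_factor=0.8,
    trinuc_nick_factor=0.8,
    hmw_nick_rate=6e-4,
    jitter_sd=0.01,
)

#: Frozen malignant (tumor-derived) component: heavier sub-nucleosomal
#: trimming (pronounced 145 bp shoulder), shorter linker remnants,
#: di-nucleosome peak near 300 bp, almost no chromatin above ~500 bp.
MALIGNANT_PARAMS = CohortParams(
    weights=_weights_tuple(
        {
            "CHROMATOSOME": 0.2731,
            "CORE": 0.1565,
            "SUBNUC": 0.4624,
            "DINUC": 0.1070,
            "TRINUC": 0.0010,
            "HIGH_MW": 0.00203,
        }
    ),
    chromo_peak_mass=0.08,
    chromo_tail_left=30.0,
    chromo_tail_right=18.0,
    subnuc_decay=0.18,
    subnuc_jitter=2,
    dinuc_center=300.0,
    dinuc_sd=8.0,
    p_site_nick=0.2116,
    protected_factor=0.12,
    dinuc_nick_factor=0.8,
    trinuc_nick_factor=0.8,
    hmw_nick_rate=6e-4,
    jitter_sd=0.01,
)


def _make_presets() -> dict[str, CohortParams]:
    # healthy-7 and healthy-109 share the chromatin mixture and differ only
    # in the high-MW share: the two healthy experiments they emulate report
    # different weakly-fragmented levels (WF ~23% vs mean DII 0.134).
    healthy7 = CohortParams(
        weights=_weights_tuple(_with_hmw(_HEALTHY_CHROMATIN, 0.1674)),
        **_HEALTHY_BASE,
    )
    healthy109 = CohortParams(
        weights=_weights_tuple(_with_hmw(_HEALTHY_CHROMATIN, 0.0638)),
        **_HEALTHY_BASE,
    )
    crc = replace(MALIGNANT_PARAMS, maf_pct=100.0)
    return {
        "healthy-7": healthy7,
        "healthy-109": healthy109,
        "crc-allstage": crc,
    }


PRESETS = _make_presets()


def get_preset(name: str, maf_pct: float | None = None) -> CohortParams:
    """Look up a named cohort preset.

    ``crc-metastatic`` requires ``maf_pct`` and is the healthy-7 background
    mixed with the malignant component at that weight.
    """
    if name == "crc-metastatic":
        if maf_pct is None:
            raise ValueError("crc-metastatic preset requires maf_pct")
        return malignant_mixture(PRESETS["healthy-7"], maf_pct)
    try:
        preset = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: "
            f"{sorted(PRESETS) + ['crc-metastatic']}"
        ) from None
    if maf_pct is not None:
        return malignant_mixture(preset, maf_pct)
    return preset


def malignant_mixture(healthy: CohortParams, maf_pct: float) -> CohortParams:
    """Cohort parameters mixing the malignant component at weight MAF/100."""
    if not 0.0 <= maf_pct <= 100.0:
        raise ValueError(f"maf_pct must lie in [0, 100], got {maf_pct}")
    return replace(healthy, maf_pct=float(maf_pct))


# ---------------------------------------------------------------------------
# Molecule generation
# ---------------------------------------------------------------------------


def _trunc_exponential(
    scale: float, upper: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer-floored exponential magnitudes truncated (not clipped) at
    ``upper`` so no probability mass piles up at the boundary."""
    u = rng.random(n)
    cap = 1.0 - math.exp(-(upper + 1) / scale)
    return np.floor(-scale * np.log1p(-u * cap)).astype(np.int64)


def _triangular_int(
    half: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric integer dispersion on [-half, half] peaked at 0
    (binomial-shaped)."""
    if half <= 0:
        return np.zeros(n, dtype=np.int64)
    return rng.binomial(2 * half, 0.5, n) - half


def _class_lengths(
    cls: np.ndarray, params: CohortParams, model: NucleosomeModel, rng: np.random.Generator
) -> np.ndarray:
    n = len(cls)
    lengths = np.zeros(n, dtype=np.int32)
    idx = np.flatnonzero(cls == _CLASS_INDEX["CHROMATOSOME"])
    if len(idx):
        # 166 ± 1 bp core peak plus asymmetric linker-remnant dispersion: the
        # protection boundary varies with how much inter-nucleosomal linker
        # remains attached, producing the broad monomodal 80-260 bp mono-
        # nucleosome population with its mode at the chromatosome length.
        base = model.chromatosome_len + rng.choice(
            [-1, 0, 1], size=len(idx), p=[0.25, 0.5, 0.25]
        )
        # right side: exponential linker remnants; left side: a flat
        # trimming continuum into the core-particle range
        s_l, s_r = params.chromo_tail_left, params.chromo_tail_right
        p_left = s_l / (s_l + 4.0 * s_r)
        u = rng.random(len(idx))
        peak = u < params.chromo_peak_mass
        right = u >= params.chromo_peak_mass + (1 - params.chromo_peak_mass) * p_left
        mag = np.where(
            right,
            _trunc_exponential(s_r, 94, len(idx), rng),
            -rng.integers(0, int(s_l) + 1, len(idx)),
        ).astype(np.int32)
        mag[peak] = 0  # defined chromatosome structures at 166 +- 1
        lengths[idx] = base + mag
    idx = np.flatnonzero(cls == _CLASS_INDEX["CORE"])
    # core-particle family with end breathing: 144-160 bp
    lengths[idx] = rng.integers(model.core_len - 3, 161, len(idx))
    idx = np.flatnonzero(cls == _CLASS_INDEX["SUBNUC"])
    if len(idx):
        k = rng.geometric(params.subnuc_decay, len(idx))
        k = np.clip(k, 1, 12)  # floor at DSP-invisible sizes (~45 bp)
        j = _triangular_int(params.subnuc_jitter, len(idx), rng)
        lengths[idx] = (
            model.chromatosome_len - np.round(model.site_spacing * k).astype(int) + j
        )
    idx = np.flatnonzero(cls == _CLASS_INDEX["DINUC"])
    if len(idx):
        x = rng.normal(params.dinuc_center, params.dinuc_sd, len(idx))
        bad = (x < 260) | (x > 440)
        while bad.any():  # resample-truncation keeps the normal shape
            x[bad] = rng.normal(params.dinuc_center, params.dinuc_sd, int(bad.sum()))
            bad = (x < 260) | (x > 440)
        lengths[idx] = np.round(x).astype(np.int32)
    idx = np.flatnonzero(cls == _CLASS_INDEX["TRINUC"])
    if len(idx):
        x = rng.normal(500.0, 20.0, len(idx))
        lengths[idx] = np.round(np.clip(x, 450, 600)).astype(np.int32)
    idx = np.flatnonzero(cls == _CLASS_INDEX["HIGH_MW"])
    if len(idx):
        x = np.exp(rng.uniform(math.log(1000.0), math.log(10000.0), len(idx)))
        lengths[idx] = np.round(x).astype(np.int32)
    return lengths


def _chromatin_lattice(
    lengths: np.ndarray,
    model: NucleosomeModel,
    rng: np.random.Generator,
    per_side: np.ndarray | int = _MAX_PER_SIDE,
) -> tuple[np.ndarray, np.ndarray]:
    """Minor-groove nick-site lattice of chromatin-protected molecules.

    Sites lie every ~10.2 bp from each protected end while they remain on
    the near half of the molecule, with per-molecule ±1 bp rotational
    jitter shared by both strands at a site.  ``per_side`` caps the ladder
    at the number of accessible wrap sites per protected end (7 per
    mono-nucleosome wrap: naked linker remnants beyond the wrap carry no
    regular lattice).  The two half-ladders are kept more than one
    vicinity-window apart so opposing nicks can only pair at the same site.
    Returns (pos, valid) of shape (n, _N_COLS).
    """
    n = len(lengths)
    pos = np.zeros((n, _N_COLS), dtype=np.int32)
    valid = np.zeros((n, _N_COLS), dtype=bool)
    j = np.arange(1, _MAX_PER_SIDE + 1)
    offs = np.round(model.site_spacing * j).astype(np.int32)
    L = np.asarray(lengths)[:, None]
    margin = 3.0 + model.site_jitter
    per_side_arr = np.broadcast_to(np.asarray(per_side), (n,))[:, None]
    ok = (offs[None, :] <= (L / 2.0 - margin)) & (j[None, :] <= per_side_arr)
    if model.site_jitter > 0:
        jit = rng.binomial(2 * model.site_jitter, 0.5, (n, _MAX_PER_SIDE)) - model.site_jitter
        jit2 = rng.binomial(2 * model.site_jitter, 0.5, (n, _MAX_PER_SIDE)) - model.site_jitter
    else:
        jit = jit2 = np.zeros((n, _MAX_PER_SIDE), dtype=np.int64)
    pos[:, :_MAX_PER_SIDE] = np.where(ok, offs[None, :] + jit, 0)
    pos[:, _MAX_PER_SIDE:] = np.where(ok, L - offs[None, :] - jit2, 0)
    valid[:, :_MAX_PER_SIDE] = ok
    valid[:, _MAX_PER_SIDE:] = ok
    return pos, valid


def _draw_nicks(
    valid: np.ndarray,
    p: np.ndarray,
    protected_factor: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli nicks per strand with one-sided accessibility.

    Nuclease attack is one-sided: per molecule one strand faces the solvent
    (per-site probability ``p``) while the opposite strand path is shielded
    (``p * protected_factor``); which physical strand is exposed is random.
    This reproduces a high molecule-level nicked fraction while one strand
    frequently survives intact.
    """
    n = valid.shape[0]
    watson_exposed = rng.random(n) < 0.5
    p_w = p * np.where(watson_exposed, 1.0, protected_factor)
    p_c = p * np.where(watson_exposed, protected_factor, 1.0)
    watson = valid & (rng.random(valid.shape) < p_w[:, None])
    crick = valid & (rng.random(valid.shape) < p_c[:, None])
    return watson, crick


def _simulate_component(
    params: CohortParams,
    n: int,
    model: NucleosomeModel,
    rng: np.random.Generator,
    source_code: int,
) -> MoleculeSet:
    weights = np.asarray(params.weights)
    cls = rng.choice(len(CLASSES), size=n, p=weights).astype(np.int8)
    lengths = _class_lengths(cls, params, model, rng)

    pos = np.zeros((n, _N_COLS), dtype=np.int32)
    valid = np.zeros((n, _N_COLS), dtype=bool)
    hmw = cls == _HIGH_MW
    chromatin = ~hmw
    if chromatin.any():
        # nicking happens at the minor-groove sites of the terminal
        # nucleosome wraps; the inter-nucleosomal linker of di-/tri-
        # nucleosomes carries no regular lattice
        per_side = np.full(len(cls), model.n_groove_sites // 2)
        cp, cv = _chromatin_lattice(
            lengths[chromatin], model, rng, per_side[chromatin]
        )
        pos[chromatin] = cp
        valid[chromatin] = cv

    # Per-site nick probability, scaled per structural family.
    p = np.full(n, params.p_site_nick)
    p[cls == _CLASS_INDEX["DINUC"]] *= params.dinuc_nick_factor
    p[cls == _CLASS_INDEX["TRINUC"]] *= params.trinuc_nick_factor
    watson, crick = _draw_nicks(valid, p, params.protected_factor, rng)

    # High-MW chromatin: sparse Poisson nicking per strand, positions free.
    if hmw.any():
        idx = np.flatnonzero(hmw)
        Lh = lengths[idx]
        for half, strand in ((0, watson), (_MAX_PER_SIDE, crick)):
            m = rng.poisson(params.hmw_nick_rate * Lh)
            m = np.minimum(m, _MAX_PER_SIDE)
            cols = np.arange(_MAX_PER_SIDE)
            sel = cols[None, :] < m[:, None]
            p_h = rng.integers(1, Lh[:, None], (len(idx), _MAX_PER_SIDE))
            pos[idx, half : half + _MAX_PER_SIDE] = np.where(sel, p_h, 0)
            valid[idx, half : half + _MAX_PER_SIDE] |= sel
            strand[idx, half : half + _MAX_PER_SIDE] = sel

    return MoleculeSet(
        ds_len=lengths,
        pos=pos,
        valid=valid,
        watson=watson,
        crick=crick,
        origin=cls,
        source=np.full(n, source_code, dtype=np.int8),
    )


def simulate_molecules(
    params: CohortParams,
    n: int,
    seed: int | np.random.Generator,
    model: NucleosomeModel = DEFAULT_MODEL,
) -> MoleculeSet:
    """Draw ``n`` molecules from a cohort's class mixture and nick them.

    With ``maf_pct > 0`` each molecule is malignant with probability
    MAF/100 and is then drawn from the frozen malignant component.  The
    malignant indicator uses a dedicated leading uniform draw and the two
    components use spawned child streams, so cohorts simulated from the same
    seed at different MAF values are coupled: raising the MAF only converts
    a nested subset of molecules from healthy-like to malignant (common
    random numbers; see docs/methods.md).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    child_h, child_m = rng.spawn(2)
    healthy = _simulate_component(replace(params, maf_pct=0.0), n, model, child_h, 0)
    if params.maf_pct <= 0:
        return healthy
    malignant = _simulate_component(MALIGNANT_PARAMS, n, model, child_m, 1)
    take_mal = u < params.maf_pct / 100.0
    out = healthy
    for name in ("ds_len", "pos", "valid", "watson", "crick", "origin", "source"):
        arr_h = getattr(healthy, name)
        arr_m = getattr(malignant, name)
        arr = np.where(
            take_mal[:, None] if arr_h.ndim == 2 else take_mal, arr_m, arr_h
        )
        setattr(out, name, arr)
    return out


# ---------------------------------------------------------------------------
# Readouts
# ---------------------------------------------------------------------------


def _counts_to_fragment_set(lengths: np.ndarray, assay: str) -> FragmentSet:
    if lengths.size == 0:
        return FragmentSet(assay=assay, counts={})
    binned = np.bincount(lengths)
    nz = np.flatnonzero(binned)
    return FragmentSet(
        assay=assay, counts={int(l): int(binned[l]) for l in nz}
    )


def _row_groups(sub: MoleculeSet) -> Iterator[np.ndarray]:
    """Row groups of similar site-column usage (keeps the segment-counting
    broadcasts narrow): mono-nucleosome family, then di-, then tri-nucleosomes."""
    mono = np.isin(sub.origin, [0, 1, 2])
    if mono.any():
        yield mono
    for code in (3, 4):
        rows = sub.origin == code
        if rows.any():
            yield rows


def _dsp_fast(
    mols: MoleculeSet, model: NucleosomeModel, rng: np.random.Generator
) -> np.ndarray:
    # Peel-off randomness is drawn on the full, fixed shape first so that
    # coupled cohorts (common random numbers across MAF values) stay aligned.
    peel_draw = rng.random((len(mols), _N_COLS + 1), dtype=np.float32)
    keep_rows = mols.origin != _HIGH_MW
    sub = mols.select(keep_rows)
    peel_draw = peel_draw[keep_rows]
    if len(sub) == 0:
        return np.empty(0, dtype=np.int32)

    out = []
    for rows in _row_groups(sub):
        cols = np.flatnonzero(sub.valid[rows].any(axis=0))
        pos = sub.pos[np.ix_(rows, cols)]
        watson = sub.watson[np.ix_(rows, cols)]
        crick = sub.crick[np.ix_(rows, cols)]
        n, k = pos.shape
        ends = sub.ds_len[rows][:, None].astype(np.int32)

        # Opposing nicks at the same minor-groove site form a double-strand
        # break; the duplex splits at that coordinate.
        dsb = watson & crick
        split = np.where(dsb, pos, ends).astype(np.int32)
        split.sort(axis=1)
        bounds = np.concatenate([np.zeros((n, 1), np.int32), split, ends], axis=1)
        segs = np.diff(bounds, axis=1)  # (n, k+1)
        seg_ok = segs > 0

        rw = watson & ~dsb
        rc = crick & ~dsb
        cw = _count_nicks_in_segments(bounds, pos, rw)
        cc = _count_nicks_in_segments(bounds, pos, rc)
        recovered = (cw == 0) | (cc == 0)

        keep = seg_ok & recovered
        short = segs < model.dsp_peel_len
        keep &= ~short | (peel_draw[rows][:, : k + 1] < (1.0 - model.peel_discard_prob))
        keep &= (segs >= model.dsp_min_len) & (segs <= model.wgs_max_len)
        out.append(segs[keep])
    return np.concatenate(out).astype(np.int32)


def _pair_opposing_nicks(
    watson: Sequence[int], crick: Sequence[int], vicinity: int
) -> list[tuple[int, int]]:
    """Greedy pairing of opposing nicks within the vicinity window.

    Watson nicks are visited left to right; each takes the nearest unused
    crick nick within ``vicinity`` bp.
    """
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    crick = list(crick)
    for w in watson:
        best_j, best_d = None, vicinity + 1
        for j, c in enumerate(crick):
            if j in used:
                continue
            d = abs(w - c)
            if d < best_d:
                best_j, best_d = j, d
        if best_j is not None and best_d <= vicinity:
            used.add(best_j)
            pairs.append((w, crick[best_j]))
    return pairs


def dsp_segments(
    mol: Molecule, model: NucleosomeModel = DEFAULT_MODEL
) -> list[tuple[int, bool]]:
    """Duplex segments of one molecule under the DSP rules, pre peel-off.

    Returns ``(length, recovered)`` per segment: opposing nick pairs within
    the vicinity window split the duplex at the watson coordinate, and a
    segment is recoverable iff at least one of its strands carries no
    remaining nick.  Segment lengths always sum to ``ds_len``.
    """
    pairs = _pair_opposing_nicks(mol.watson_nicks, mol.crick_nicks, model.vicinity)
    split_w = {w for w, _ in pairs}
    split_c = {c for _, c in pairs}
    splits = sorted(set(split_w))
    bounds = [0, *splits, mol.ds_len]
    rem_w = [p for p in mol.watson_nicks if p not in split_w]
    rem_c = [p for p in mol.crick_nicks if p not in split_c]
    out = []
    for a, b in zip(bounds, bounds[1:]):
        if b <= a:
            continue
        nw = sum(1 for p in rem_w if a < p < b)
        nc = sum(1 for p in rem_c if a < p < b)
        out.append((b - a, nw == 0 or nc == 0))
    return out


def ssp_pieces(
    mol: Molecule, model: NucleosomeModel = DEFAULT_MODEL
) -> list[int]:
    """Reported single-strand piece lengths of one molecule, pre filtering.

    Each strand releases n+1 pieces from its n nicks; every nick-bounded
    piece reads ``stagger`` nt longer than the underlying run (the 3'
    overhang left by staggered cleavage survives single-strand library
    preparation but not duplex end repair).  Intact strands of sub-
    nucleosomal trim products carry the overhang of the cut that made them.
    """
    out: list[int] = []
    trimmed = mol.origin == "SUBNUC"
    for nicks in (mol.watson_nicks, mol.crick_nicks):
        bounds = [0, *nicks, mol.ds_len]
        for a, b in zip(bounds, bounds[1:]):
            run = b - a
            out.append(run + model.stagger if (nicks or trimmed) else run)
    return out


def dsp_readout(
    molecules: MoleculeSet | Iterable[Molecule],
    model: NucleosomeModel = DEFAULT_MODEL,
    seed: int | np.random.Generator = 0,
) -> FragmentSet:
    """Double-strand library readout: duplex fragments in [30, 1000] bp.

    High-MW molecules never enter sequencing libraries.  Duplex segments
    shorter than a full nucleosome turn peel off with probability
    ``model.peel_discard_prob``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(molecules, MoleculeSet):
        lengths = _dsp_fast(molecules, model, rng)
        return _counts_to_fragment_set(lengths, "DSP")
    keep: list[int] = []
    for mol in molecules:
        if mol.origin == "HIGH_MW":
            continue
        for length, recovered in dsp_segments(mol, model):
            if not recovered:
                continue
            if length < model.dsp_peel_len and rng.random() >= 1.0 - model.peel_discard_prob:
                continue
            if model.dsp_min_len <= length <= model.wgs_max_len:
                keep.append(length)
    return _counts_to_fragment_set(np.asarray(keep, dtype=np.int32), "DSP")


def _ssp_fast(
    mols: MoleculeSet, model: NucleosomeModel, rng: np.random.Generator
) -> np.ndarray:
    draws = [
        rng.random((len(mols), _N_COLS + 1), dtype=np.float32) for _ in range(2)
    ]
    keep_rows = mols.origin != _HIGH_MW
    sub = mols.select(keep_rows)
    if len(sub) == 0:
        return np.empty(0, dtype=np.int32)
    # End-fraying of intact strands on attacked molecules: drawn on the full
    # fixed shape for common-random-number alignment across MAF values.
    smears = [
        np.clip(np.round(rng.normal(0.0, max(model.ssp_end_smear, 1e-9), len(mols))), -4, 4).astype(np.int32)
        for _ in range(2)
    ]
    if model.ssp_end_smear <= 0:
        smears = [np.zeros(len(mols), np.int32) for _ in range(2)]
    out = []
    strands = (sub.watson, sub.crick)
    trimmed = sub.origin == 2  # SUBNUC termini are staggered cuts
    for si, (strand, draw) in enumerate(zip(strands, draws)):
        draw = draw[keep_rows]
        smear = smears[si][keep_rows]
        other_nicked = strands[1 - si].any(axis=1)
        for rows in _row_groups(sub):
            cols = np.flatnonzero(sub.valid[rows].any(axis=0))
            pieces, ok = _strand_pieces(
                sub.ds_len[rows], sub.pos[np.ix_(rows, cols)], strand[np.ix_(rows, cols)]
            )
            nicked = strand[rows].any(axis=1)
            reported = pieces + np.where(nicked, model.stagger, 0)[:, None]
            # intact strands of nuclease-trimmed products also carry the 3'
            # overhang of the staggered cut that created the molecule
            reported[:, 0] = np.where(
                ~nicked & trimmed[rows], reported[:, 0] + model.stagger, reported[:, 0]
            )
            # an intact strand of a molecule whose sister strand is nicked has
            # frayed termini: its reported length disperses by a few nt
            frayed = ~nicked & other_nicked[rows]
            reported[:, 0] = np.where(
                frayed, reported[:, 0] + smear[rows], reported[:, 0]
            )
            weight = model.ssp_detect(reported) * model.ssp_capture(reported)
            weight *= np.where(nicked[:, None], model.ssp_survival(reported), 1.0)
            keep = ok & (draw[rows][:, : pieces.shape[1]] < weight)
            keep &= reported <= model.wgs_max_len
            out.append(reported[keep])
    return np.concatenate(out).astype(np.int32)


def ssp_readout(
    molecules: MoleculeSet | Iterable[Molecule],
    model: NucleosomeModel = DEFAULT_MODEL,
    seed: int | np.random.Generator = 0,
) -> FragmentSet:
    """Single-strand library readout: strand pieces >= ~25 nt.

    Pieces between the detection limit and the reliable-read length are
    retained with linearly ramping probability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(molecules, MoleculeSet):
        return _counts_to_fragment_set(_ssp_fast(molecules, model, rng), "SSP")
    keep: list[int] = []
    for mol in molecules:
        if mol.origin == "HIGH_MW":
            continue
        both = (mol.watson_nicks, mol.crick_nicks)
        trimmed = mol.origin == "SUBNUC"
        for si, strand_nicks in enumerate(both):
            bounds = [0, *strand_nicks, mol.ds_len]
            for a, b in zip(bounds, bounds[1:]):
                length = b - a + (model.stagger if strand_nicks or trimmed else 0)
                if not strand_nicks and both[1 - si] and model.ssp_end_smear > 0:
                    length += int(
                        np.clip(round(rng.normal(0.0, model.ssp_end_smear)), -4, 4)
                    )
                if length > model.wgs_max_len:
                    continue
                arr = np.asarray([length])
                w = float(model.ssp_detect(arr)[0]) * float(model.ssp_capture(arr)[0])
                if strand_nicks:
                    w *= float(model.ssp_survival(arr)[0])
                if rng.random() < w:
                    keep.append(length)
    return _counts_to_fragment_set(np.asarray(keep, dtype=np.int32), "SSP")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class SampleResult:
    """Per-sample output of :func:`simulate_cohort`."""

    name: str
    params: CohortParams
    seed: int
    dsp: FragmentSet | None = None
    ssp: FragmentSet | None = None
    qpcr: QpcrResult | None = None
    molecules: MoleculeSet | None = None


def _jitter_weights(
    weights: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample heterogeneity: jitter each class weight on the log-odds
    scale, then renormalize to the simplex."""
    if sd <= 0:
        return weights
    w = np.clip(weights, 1e-12, 1 - 1e-12)
    logit = np.log(w / (1 - w)) + rng.normal(0.0, sd, len(w))
    w = 1.0 / (1.0 + np.exp(-logit))
    return w / w.sum()


def simulate_cohort(
    preset: str | CohortParams,
    n_samples: int,
    n_molecules: int,
    seed: int,
    model: NucleosomeModel = DEFAULT_MODEL,
    readouts: Sequence[str] = ("dsp", "ssp", "qpcr"),
    panel: AmpliconPanel = DEFAULT_PANEL,
    maf_pct: float | None = None,
    keep_molecules: bool = False,
) -> list[SampleResult]:
    """Simulate a cohort and render each sample through the requested readouts.

    Sample ``i`` uses the generator seeded with ``seed + i``; reruns with the
    same seed are bit-identical.
    """
    params = get_preset(preset, maf_pct) if isinstance(preset, str) else preset
    if maf_pct is not None and not isinstance(preset, str):
        params = malignant_mixture(params, maf_pct)
    results = []
    for i in range(n_samples):
        sample_seed = seed + i
        rng = np.random.default_rng(sample_seed)
        w = _jitter_weights(np.asarray(params.weights), params.jitter_sd, rng)
        sample_params = replace(params, weights=tuple(w), jitter_sd=0.0)
        mols = simulate_molecules(sample_params, n_molecules, rng, model)
        res = SampleResult(
            name=f"sample_{i:03d}", params=sample_params, seed=sample_seed
        )
        if "dsp" in readouts:
            res.dsp = dsp_readout(mols, model, rng)
        if "ssp" in readouts:
            res.ssp = ssp_readout(mols, model, rng)
        if "qpcr" in readouts:
            res.qpcr = insilico_qpcr(mols, panel, sample=res.name)
        if keep_molecules:
            res.molecules = mols
        results.append(res)
    return results
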