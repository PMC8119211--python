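"""Q-PCR fractional size distribution and the DNA Integrity Index (DII).

A nested amplicon panel (default 67, 145, 320 bp at one locus) quantifies how
much template carries an intact, nick-free stretch of at least each amplicon
length.  Because longer amplicons require longer intact stretches, the
measured concentrations are nonincreasing in amplicon length, which turns the
three concentrations into a size partition:

* HF  (highly fragmented, 67–145 bp)      = 100·(C67 − C145)/C67
* MF  (mono-nucleosome, 145–320 bp)       = 100·(C145 − C320)/C67
* WF  (weakly fragmented, >320 bp)        = 100·C320/C67
* DII (integrity index)                   = C320/C67

Concentrations are unit-free: only their ratios are meaningful.  The
in-silico readout counts a simulated molecule toward C(L) when at least one
of its strands carries a nick-free contiguous run of at least L nucleotides
(runs bounded by molecule ends and nicks) — Q-PCR amplifies from a
single-strand template, so one intact strand suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AmpliconPanel",
    "QpcrResult",
    "FractionalDistribution",
    "DIIValue",
    "NestingViolationError",
    "fractional_distribution",
    "dii",
    "insilico_qpcr",
    "cohort_dii",
    "read_qpcr_table",
    "write_qpcr_table",
    "DEFAULT_PANEL",
]


class NestingViolationError(ValueError):
    """A longer amplicon measured more template than a shorter one."""


@dataclass(frozen=True)
class AmpliconPanel:
    """Ordered nested amplicon lengths (bp) at one locus."""

    lengths: tuple[int, ...] = (67, 145, 320)

    def __post_init__(self) -> None:
        if len(self.lengths) < 2:
            raise ValueError("amplicon panel needs >= 2 lengths")
        if any(b <= a for a, b in zip(self.lengths, self.lengths[1:])):
            raise ValueError("amplicon lengths must be strictly increasing")


DEFAULT_PANEL = AmpliconPanel()


@dataclass
class QpcrResult:
    """Concentration (arbitrary units, >= 0) per amplicon length."""

    concentrations: dict[int, float]
    sample: str = ""

    def __post_init__(self) -> None:
        for length, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration at {length} bp")
        lengths = sorted(self.concentrations)
        for a, b in zip(lengths, lengths[1:]):
            if self.concentrations[b] > self.concentrations[a] * (1 + 1e-12):
                raise NestingViolationError(
                    f"concentration at {b} bp ({self.concentrations[b]:g}) exceeds "
                    f"that at {a} bp ({self.concentrations[a]:g}); nested amplicons "
                    "must be nonincreasing in length"
                )

    def at(self, length: int) -> float:
        return float(self.concentrations[length])


@dataclass
class FractionalDistribution:
    """HF / MF / WF percentages; sum to 100."""

    hf_pct: float
    mf_pct: float
    wf_pct: float

    def __post_init__(self) -> None:
        for v in (self.hf_pct, self.mf_pct, self.wf_pct):
            if not -1e-9 <= v <= 100 + 1e-9:
                raise ValueError(f"fraction {v} outside [0, 100]")
        if abs(self.hf_pct + self.mf_pct + self.wf_pct - 100.0) > 1e-6:
            raise ValueError("HF + MF + WF must sum to 100")


@dataclass
class DIIValue:
    """DNA Integrity Index: ratio of >320 bp to >67 bp template."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("DII must be >= 0")


def _check_panel_result(result: QpcrResult, panel: AmpliconPanel) -> tuple[float, ...]:
    missing = [l for l in panel.lengths if l not in result.concentrations]
    if missing:
        raise ValueError(f"result lacks concentrations for amplicons {missing}")
    return tuple(result.at(l) for l in panel.lengths)


def fractional_distribution(
    result: QpcrResult, panel: AmpliconPanel = DEFAULT_PANEL
) -> FractionalDistribution:
    """HF/MF/WF percentages from a three-amplicon nested panel."""
    if len(panel.lengths) != 3:
        raise ValueError("fractional_distribution needs a three-amplicon panel")
    c_short, c_mid, c_long = _check_panel_result(result, panel)
    if c_short <= 0:
        raise ZeroDivisionError("short-amplicon concentration must be > 0")
    return FractionalDistribution(
        hf_pct=100.0 * (c_short - c_mid) / c_short,
        mf_pct=100.0 * (c_mid - c_long) / c_short,
        wf_pct=100.0 * c_long / c_short,
    )


def dii(result: QpcrResult, panel: AmpliconPanel = DEFAULT_PANEL) -> DIIValue:
    """DII = C(longest amplicon) / C(shortest amplicon)."""
    concs = _check_panel_result(result, panel)
    c_short, c_long = concs[0], concs[-1]
    if c_short <= 0:
        raise ZeroDivisionError("short-amplicon concentration must be > 0")
    return DIIValue(value=c_long / c_short)


def _max_clean_run(length: int, nicks: Sequence[int]) -> int:
    """Longest nick-free contiguous stretch on one strand."""
    bounds = [0, *sorted(nicks), length]
    return max(b - a for a, b in zip(bounds, bounds[1:]))


def insilico_qpcr(
    molecules: Iterable, panel: AmpliconPanel = DEFAULT_PANEL, sample: str = ""
) -> QpcrResult:
    """In-silico Q-PCR readout of simulated molecules.

    C(L) counts molecules possessing, on at least one strand, a nick-free
    contiguous run >= L (runs bounded by molecule ends and nicks).  Accepts
    any iterable of :class:`~cffrag.simulate.Molecule` or a
    :class:`~cffrag.simulate.MoleculeSet`.
    """
    amp = np.asarray(panel.lengths)
    counts = np.zeros(len(amp), dtype=np.int64)
    max_runs = getattr(molecules, "max_clean_runs", None)
    if max_runs is not None:
        runs = np.asarray(max_runs())
        counts = (runs[:, None] >= amp[None, :]).sum(axis=0)
    else:
        for mol in molecules:
            run = max(
                _max_clean_run(mol.ds_len, mol.watson_nicks),
                _max_clean_run(mol.ds_len, mol.crick_nicks),
            )
            counts += run >= amp
    return QpcrResult(
        concentrations={int(l): float(c) for l, c in zip(amp, counts)},
        sample=sample,
    )


@dataclass
class DiiSummary:
    mean: float
    sd: float
    median: float
    n: int
    values: list[float] = field(default_factory=list)


def cohort_dii(
    results: Sequence[QpcrResult], panel: AmpliconPanel = DEFAULT_PANEL
) -> DiiSummary:
    """Mean, SD (ddof=1 when n > 1) and median of per-sample DII values."""
    if not results:
        raise ValueError("cohort_dii needs at least one result")
    values = [dii(r, panel).value for r in results]
    arr = np.asarray(values)
    return DiiSummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        median=float(np.median(arr)),
        n=len(arr),
        values=values,
    )


def read_qpcr_table(path: str | Path) -> dict[str, QpcrResult]:
    """Read a ``sample<TAB>amplicon_bp<TAB>concentration`` TSV (with header)."""
    per_sample: dict[str, dict[int, float]] = {}
    with open(path, "rt", encoding="utf-8") as handle:
        header = handle.readline()
        if not header.lower().startswith("sample"):
            raise ValueError(f"{path}:1: expected header starting with 'sample'")
        for lineno, line in enumerate(handle, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                sample, amp_s, conc_s = line.split("\t")[:3]
                amp, conc = int(amp_s), float(conc_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row") from exc
            per_sample.setdefault(sample, {})[amp] = conc
    return {
        sample: QpcrResult(concentrations=concs, sample=sample)
        for sample, concs in per_sample.items()
    }


def write_qpcr_table(results: Sequence[QpcrResult], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("sample\tamplicon_bp\tconcentration\n")
        for r in results:
            for amp in sorted(r.concentrations):
                handle.write(f"{r.sample}\t{amp}\t{r.concentrations[amp]:.10g}\n")
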