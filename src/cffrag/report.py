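"""End-to-end healthy-vs-cancer comparison report.

``run_compare`` takes per-sample fragment sets, builds the healthy reference
mean profile, computes each sample's feature panel and ΔS/ΔV curves against
it, optionally the MAF trend, and writes deterministic TSV/JSON outputs that
embed the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .io import FragmentSet, SizeProfile, build_profile, write_profile
from .profile import (
    FeaturePanel,
    delta_s,
    delta_v,
    feature_panel,
    maf_trend,
    reference_mean,
)

logger = logging.getLogger("cffrag")

__all__ = ["RunConfig", "CompareReport", "run_compare", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for profile comparison."""

    support: tuple[int, int] = (30, 440)
    smooth_halfwidth: int = 2
    min_prominence: float = 0.15
    amplicon_panel: tuple[int, ...] = (67, 145, 320)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.support
        if not (20 <= lo < hi <= 1500):
            raise ValueError(f"support must satisfy 20 <= lo < hi <= 1500, got {self.support}")
        if self.smooth_halfwidth < 0:
            raise ValueError("smooth_halfwidth must be >= 0")
        if not 0 <= self.min_prominence:
            raise ValueError("min_prominence must be >= 0")
        if any(b <= a for a, b in zip(self.amplicon_panel, self.amplicon_panel[1:])):
            raise ValueError("amplicon panel must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("support", "amplicon_panel"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class CompareReport:
    config: RunConfig
    reference: SizeProfile
    panels: dict[str, FeaturePanel]
    delta_s_curves: dict[str, "object"]
    delta_v_curves: dict[str, "object"]
    trend: "object | None" = None
    mafs: dict[str, float] = field(default_factory=dict)


def run_compare(
    samples: Mapping[str, FragmentSet],
    reference_samples: Mapping[str, FragmentSet],
    config: RunConfig = RunConfig(),
    mafs: Mapping[str, float] | None = None,
) -> CompareReport:
    """Compare each sample against the mean profile of the reference cohort."""
    if not samples or not reference_samples:
        raise ValueError("need at least one sample and one reference sample")
    ref_profiles = [
        build_profile(fs, config.support) for fs in reference_samples.values()
    ]
    assays = {p.assay for p in ref_profiles}
    reference = reference_mean(ref_profiles)
    logger.info(
        "reference mean built from %d samples (assay %s, support %s)",
        len(ref_profiles), reference.assay, config.support,
    )
    panels: dict[str, FeaturePanel] = {}
    ds_curves = {}
    dv_curves = {}
    for name, fs in samples.items():
        if fs.assay != reference.assay:
            raise ValueError(
                f"sample {name!r} assay {fs.assay!r} does not match reference "
                f"assay {reference.assay!r}"
            )
        prof = build_profile(fs, config.support)
        panel = feature_panel(
            prof,
            reference=reference,
            maf_pct=None if mafs is None else mafs.get(name),
        )
        panels[name] = panel
        ds_curves[name] = delta_s(prof, reference)
        dv_curves[name] = delta_v(prof, reference)
        logger.info("sample %s: %s", name, panel.as_dict())
    trend = None
    if mafs is not None and len(samples) >= 3 and set(mafs) >= set(samples):
        trend = maf_trend(
            [panels[n] for n in samples], [mafs[n] for n in samples]
        )
    return CompareReport(
        config=config,
        reference=reference,
        panels=panels,
        delta_s_curves=ds_curves,
        delta_v_curves=dv_curves,
        trend=trend,
        mafs=dict(mafs or {}),
    )


def write_report(report: CompareReport, outdir: str | Path) -> None:
    """Write the comparison report: JSON feature panels and TSV curves.

    Outputs are byte-identical across reruns with the same inputs and
    configuration; every file embeds the config hash and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": report.config.digest(), "seed": report.config.seed}
    payload = {
        **stamp,
        "config": asdict(report.config),
        "panels": {n: p.as_dict() for n, p in report.panels.items()},
        "maf_trend": None
        if report.trend is None
        else {
            "correlations": report.trend.correlations,
            "n_samples": report.trend.n_samples,
            "mafs": report.trend.mafs,
        },
    }
    for key in ("panels",):
        for name, d in payload[key].items():
            payload[key][name] = {
                k: (None if v is None else round(v, 10) if isinstance(v, float) else v)
                for k, v in d.items()
            }
    with open(outdir / "features.json", "wt", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    write_profile(report.reference, outdir / "reference_profile.tsv")
    header = f"# config_hash={stamp['config_hash']} seed={stamp['seed']}\n"
    for label, curves in (
        ("delta_s", report.delta_s_curves),
        ("delta_v", report.delta_v_curves),
    ):
        for name, curve in curves.items():
            path = outdir / f"{label}_{name}.tsv"
            with open(path, "wt", encoding="utf-8", newline="\n") as fh:
                fh.write(header)
                fh.write("length\tvalue\n")
                for l, v in zip(curve.lengths, curve.values):
                    fh.write(f"{l}\t{v:.10g}\n")
    logger.info("report written to %s", outdir)
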