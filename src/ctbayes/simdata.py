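"""Synthetic Ct datasets with known per-gene effects and detection censoring.

The generator draws a latent Gaussian Ct per well (assay baseline + group
effect + noise) and censors wells whose latent Ct exceeds the limit of
detection, emitting them as undetected. Group effects are dCt shifts of the
CD group relative to controls within each age stratum; negative shifts mean
up-regulation in CD (fewer cycles to threshold). A single integer seed
governs all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .qpcr import CtMatrix, write_ct_table

STRATA = ("cd_child", "ctrl_child", "cd_adult", "ctrl_adult")

COMPARISONS = ("cd_vs_ctrl_child", "cd_vs_ctrl_adult", "cd_child_vs_cd_adult")


@dataclass(frozen=True)
class AssaySpec:
    """Generating parameters for one assay.

    ``effects`` maps age stratum ("child"/"adult") to the CD-minus-control
    dCt shift in cycles; omitted strata default to 0 (null).
    """

    assay_id: str
    gene: str
    role: str = "target"
    category: str = "none"
    baseline_ct: float = 27.0
    sd: float = 1.0
    effects: Mapping[str, float] = field(default_factory=dict)

    def effect(self, age_group: str) -> float:
        return float(self.effects.get(age_group, 0.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Study design, assay panel and censoring threshold for one simulation."""

    n_cd_children: int = 13
    n_ctrl_children: int = 7
    n_cd_adults: int = 6
    n_ctrl_adults: int = 5
    # per-stratum (mean, sd) of age in years
    age_means_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "cd_child": (5.6, 0.6),
            "ctrl_child": (8.1, 2.2),
            "cd_adult": (38.3, 3.4),
            "ctrl_adult": (50.6, 10.9),
        }
    )
    assays: tuple[AssaySpec, ...] = ()
    lod_ct: float = 35.0
    seed: int = 0

    def __post_init__(self):
        if not self.assays:
            object.__setattr__(self, "assays", tuple(default_panel()))
        self.validate()

    def validate(self) -> None:
        sizes = {
            "n_cd_children": self.n_cd_children,
            "n_ctrl_children": self.n_ctrl_children,
            "n_cd_adults": self.n_cd_adults,
            "n_ctrl_adults": self.n_ctrl_adults,
        }
        for name, n in sizes.items():
            if n < 2:
                raise ConfigurationError(f"{name} must be >= 2, got {n}")
        if self.lod_ct <= 0:
            raise ConfigurationError(f"lod_ct must be positive, got {self.lod_ct}")
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("assay ids must be unique")
        for a in self.assays:
            if a.sd < 0:
                raise ConfigurationError(f"assay {a.assay_id}: sd must be >= 0")
            if a.role not in ("target", "housekeeping", "reference-candidate"):
                raise ConfigurationError(f"assay {a.assay_id}: unknown role {a.role!r}")
        for stratum, (_, sd) in self.age_means_sd.items():
            if sd < 0:
                raise ConfigurationError(f"age sd for {stratum} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        assays = tuple(
            AssaySpec(**spec) for spec in raw.pop("assays", [])
        )
        if "age_means_sd" in raw:
            raw["age_means_sd"] = {
                k: tuple(v) for k, v in raw["age_means_sd"].items()
            }
        try:
            return cls(assays=assays, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad simulation config {path}: {exc}") from exc


def _taqman_id(i: int) -> str:
    return f"Hs{90000100 + i * 37:08d}_m1"


def default_panel() -> list[AssaySpec]:
    """48-assay panel: 3 commercial housekeeping assays that are too noisy to
    normalize with, 2 highly stable reference candidates, 38 analyzable target
    assays (one gene carried by two probes), 2 assays below the limit of
    detection everywhere and 3 detected only in a minority of samples."""
    panel: list[AssaySpec] = []

    for i, (gene, base) in enumerate([("RPLP0", 18.0), ("HPRT1", 24.0), ("RN18S1", 12.0)]):
        panel.append(
            AssaySpec(_taqman_id(i), gene, role="housekeeping", baseline_ct=base, sd=2.0)
        )

    # stable reference candidates promoted to endogenous references downstream
    panel.append(AssaySpec(_taqman_id(3), "PUS10", role="reference-candidate",
                           category="CD-locus", baseline_ct=26.0, sd=0.12))
    panel.append(AssaySpec(_taqman_id(4), "GLB1", role="reference-candidate",
                           category="none", baseline_ct=24.5, sd=0.12))

    up = {"child": -1.2, "adult": -1.2}
    targets: list[tuple[str, str, dict[str, float]]] = [
        # similarly up-regulated in both strata
        ("C2orf74", "CD-locus", dict(up)),
        ("CCR6", "Th17", dict(up)),
        ("FASLG", "CD-locus", dict(up)),
        ("JAK2", "Th17", dict(up)),
        ("IL23A", "both", dict(up)),
        ("TAGAP", "CD-locus", dict(up)),
        ("UBE2L3", "CD-locus", dict(up)),
        # altered only in adults
        ("IL1RL1", "CD-locus", {"adult": -1.6}),
        ("CD28", "CD-locus", {"adult": -1.4}),
        ("STAT3", "Th17", {"adult": -1.4}),
        ("TMEM187", "CD-locus", {"adult": -1.4}),
        ("VAMP3", "Th17", {"adult": -1.4}),
        ("ZFP36L1", "CD-locus", {"adult": -1.4}),
        # altered only in children
        ("TNFSF18", "CD-locus", {"child": -1.6}),
        ("ICOSLG", "CD-locus", {"child": 1.5}),
        # altered in both, stronger in adults
        ("CCR4", "Th17", {"child": -0.8, "adult": -2.0}),
        ("IL6", "Th17", {"child": -0.8, "adult": -1.8}),
        ("IL18RAP", "CD-locus", {"child": -0.7, "adult": -1.5}),
        ("PLEK", "CD-locus", {"child": -0.7, "adult": -1.5}),
        # altered in both, stronger in children (down-regulated in CD)
        ("C1orf106", "CD-locus", {"child": 1.6, "adult": 0.7}),
    ]
    null_genes = [
        "SH2B3", "IL18R1", "CTLA4", "ICOS", "IL12A", "LPP", "REL", "RGS1",
        "SOCS1", "PTPN2", "ITGA4", "THEMIS", "ETS1", "RUNX3", "CCR3",
        "IRAK1", "POU2AF1",
    ]
    targets += [(g, "CD-locus", {}) for g in null_genes]

    rng = np.random.default_rng(20160209)  # fixed: panel is part of the default config
    baselines = rng.uniform(24.0, 30.0, size=len(targets) + 1)
    for i, (gene, cat, eff) in enumerate(targets):
        panel.append(
            AssaySpec(_taqman_id(10 + i), gene, category=cat,
                      baseline_ct=round(float(baselines[i]), 2),
                      sd=1.0, effects=eff)
        )
    # second probe for the same gene (membrane-bound isoform), null effect
    panel.append(AssaySpec("Hs01073297_m1", "IL1RL1", category="CD-locus",
                           baseline_ct=round(float(baselines[-1]), 2), sd=1.0,
                           effects={"adult": -1.6}))

    # below the limit of detection in every sample
    panel.append(AssaySpec(_taqman_id(60), "ADAD1", baseline_ct=45.0, sd=0.5))
    panel.append(AssaySpec(_taqman_id(61), "OLIG3", baseline_ct=45.0, sd=0.5))
    # detected in a minority of samples; IL21 more detectable in CD
    panel.append(AssaySpec(_taqman_id(62), "IL17F", baseline_ct=36.5, sd=1.2))
    panel.append(AssaySpec(_taqman_id(63), "IL21", baseline_ct=37.2, sd=1.2,
                           effects={"child": -2.2, "adult": -2.2}))
    panel.append(AssaySpec(_taqman_id(64), "IL22", baseline_ct=36.5, sd=1.2))
    assert len(panel) == 48
    return panel


def _stratum_of(status: str, age_group: str) -> str:
    return ("cd_" if status == "CD" else "ctrl_") + age_group


def generate_dataset(
    config: SimulationConfig,
) -> tuple[CtMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one dataset under ``config``.

    Returns ``(ct, samples, assays, truth)`` where ``truth`` holds, per assay
    and comparison, the true mean dCt difference, a null indicator and a
    direction label (``up``/``down`` refer to expression of the first group of
    the comparison; lower dCt = higher expression).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    design = [
        ("cd_child", "CD", "child", config.n_cd_children),
        ("ctrl_child", "control", "child", config.n_ctrl_children),
        ("cd_adult", "CD", "adult", config.n_cd_adults),
        ("ctrl_adult", "control", "adult", config.n_ctrl_adults),
    ]
    rows = []
    for stratum, status, age_group, n in design:
        mean, sd = config.age_means_sd.get(stratum, (30.0, 5.0))
        ages = rng.normal(mean, sd, size=n)
        ages = np.abs(ages)  # truncate at 0 by reflection; only summaries matter
        ages[ages == 0] = 0.1
        for j in range(n):
            rows.append(
                {
                    "sample_id": f"{stratum}_{j + 1:02d}",
                    "age_years": round(float(ages[j]), 2),
                    "age_group": age_group,
                    "status": status,
                }
            )
    samples = pd.DataFrame(rows).set_index("sample_id")

    latent = np.empty((len(samples), len(config.assays)))
    for k, spec in enumerate(config.assays):
        shift = np.array(
            [
                spec.effect(ag) if st == "CD" else 0.0
                for st, ag in zip(samples["status"], samples["age_group"])
            ]
        )
        latent[:, k] = spec.baseline_ct + shift + rng.normal(0.0, spec.sd, len(samples))
    observed = np.where(latent > config.lod_ct, np.nan, latent)
    ct = CtMatrix(
        pd.DataFrame(observed, index=samples.index,
                     columns=[a.assay_id for a in config.assays])
    )

    assays = pd.DataFrame(
        {
            "assay_id": [a.assay_id for a in config.assays],
            "gene": [a.gene for a in config.assays],
            "role": [a.role for a in config.assays],
            "category": [a.category for a in config.assays],
        }
    ).set_index("assay_id")

    truth = ground_truth(config)
    return ct, samples, assays, truth


def ground_truth(config: SimulationConfig) -> pd.DataFrame:
    """True mean dCt differences per assay for the three primary comparisons."""
    rows = []
    for spec in config.assays:
        diffs = {
            "cd_vs_ctrl_child": spec.effect("child"),
            "cd_vs_ctrl_adult": spec.effect("adult"),
            "cd_child_vs_cd_adult": spec.effect("child") - spec.effect("adult"),
        }
        for comparison, diff in diffs.items():
            direction = "none" if diff == 0 else ("up" if diff < 0 else "down")
            rows.append(
                {
                    "assay_id": spec.assay_id,
                    "gene": spec.gene,
                    "comparison": comparison,
                    "true_diff": diff,
                    "is_null": diff == 0.0,
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


def write_dataset(
    ct: CtMatrix,
    samples: pd.DataFrame,
    assays: pd.DataFrame,
    out_dir,
    truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the CSV trio (plus optional truth table) consumed downstream."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct": out / "ct_matrix.csv",
        "samples": out / "samples.csv",
        "assays": out / "assays.csv",
    }
    write_ct_table(ct, paths["ct"])
    samples.to_csv(paths["samples"])
    assays.to_csv(paths["assays"])
    if truth is not None:
        paths["truth"] = out / "ground_truth.csv"
        truth.to_csv(paths["truth"], index=False)
    return paths
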