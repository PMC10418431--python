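"""Synthetic jam storage datasets with the statistical structure of the
study conditions.

Four formulations are emulated — FA (conventional, synthetic HM pectin),
FB (light, LM pectin + xanthan), FC (conventional, passion-fruit-peel HM
pectin) and FD (light, LM pectin + xanthan) — sampled over 0-120 days of
storage in triplicate.  Each dependent property follows its published
linear time model (intercept, slope per day) plus Gaussian noise; the FC
hardness series is time-invariant, mirroring its non-significant F test.
Covariates (pH, acidity) are drawn inside the tabulated per-formulation
ranges, and each formulation carries a fixed five-component mass-fraction
profile (conventional ~67 degBrix, light ~37 degBrix) with a small jitter.

The default grid — every other day from 0 to 120 plus the four analytic
days {0, 30, 90, 120}, trimmed deterministically — yields exactly 680
records, splittable 585/55/40.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ann import SplitSpec, random_split
from .stats import fit_linear

__all__ = [
    "FormulationSpec",
    "GeneratorConfig",
    "PROPERTY_COLUMNS",
    "RESPONSE_COLUMNS",
    "default_specs",
    "generate_dataset",
    "write_records_csv",
    "write_worksheet_bundle",
    "recovery_check",
]

#: All generated dependent properties (column names of the record table).
PROPERTY_COLUMNS = (
    "hardness", "water_activity", "adhesiveness",
    "anthocyanins", "reducing_sugars", "soluble_solids",
)

#: The three network response variables.
RESPONSE_COLUMNS = ("hardness", "water_activity", "adhesiveness")

#: Default noise standard deviations per property (units of the property).
DEFAULT_SIGMAS = {
    "hardness": 0.05,          # N
    "water_activity": 0.005,
    "adhesiveness": 0.5,       # mJ
    "anthocyanins": 1.0,       # mg / 100 g
    "reducing_sugars": 0.5,    # %
    "soluble_solids": 0.5,     # degBrix
}

# Mass-fraction profiles over the five descriptor-bearing components.
_CONVENTIONAL_PROFILE = {
    "water": 0.330, "citric_acid": 0.004, "glucose": 0.215,
    "sucrose": 0.450, "anthocyanin": 0.001,
}
_LIGHT_PROFILE = {
    "water": 0.625, "citric_acid": 0.007, "glucose": 0.140,
    "sucrose": 0.225, "anthocyanin": 0.003,
}


@dataclass(frozen=True)
class FormulationSpec:
    """Generating model for one formulation.

    ``models`` maps property name to (intercept, slope per day); a zero
    slope encodes a storage-stable (time-invariant) property.
    """

    id: str
    pct_HM_pectin: float
    pct_LM_pectin: float
    pct_xanthan: float
    pH_range: tuple[float, float]
    acidity_range: tuple[float, float]
    composition: dict[str, float]
    models: dict[str, tuple[float, float]]
    sigmas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMAS))

    def __post_init__(self):
        missing = set(PROPERTY_COLUMNS) - set(self.models)
        if missing:
            raise ValueError(f"{self.id}: missing generating models for {sorted(missing)}")
        if any(s < 0 for s in self.sigmas.values()):
            raise ValueError("noise sigmas must be non-negative")

    def mean(self, prop: str, time) -> np.ndarray:
        a, b = self.models[prop]
        return a + b * np.asarray(time, float)


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling grid, replication, seed and split counts."""

    times: tuple[float, ...] = tuple(range(0, 121, 2))
    replicates: int = 3
    seed: int = 0
    n_records: int | None = 680
    split: SplitSpec | None = None
    composition_jitter: float = 0.02  # relative

    def __post_init__(self):
        if any(t < 0 or t > 120 for t in self.times):
            raise ValueError("storage times must lie in [0, 120] days")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def default_specs() -> tuple[FormulationSpec, ...]:
    """The four formulation specs with the published generating models.

    Properties without a published time model get a constant mean chosen
    inside the tabulated value ranges.
    """
    def spec(fid, hm, lm, xf, ph, ac, profile, models):
        return FormulationSpec(
            id=fid, pct_HM_pectin=hm, pct_LM_pectin=lm, pct_xanthan=xf,
            pH_range=ph, acidity_range=ac, composition=dict(profile),
            models=models,
        )

    return (
        spec("FA", 0.6, 0.0, 0, (3.32, 3.45), (0.56, 0.58), _CONVENTIONAL_PROFILE, {
            "hardness": (11.64, -0.027),
            "water_activity": (0.75, 0.0),
            "adhesiveness": (86.29, 0.583),
            "anthocyanins": (30.0, 0.0),
            "reducing_sugars": (60.0, 0.0),
            "soluble_solids": (47.85, 0.046),
        }),
        spec("FB", 0.0, 1.2, 2, (3.63, 3.99), (0.34, 0.40), _LIGHT_PROFILE, {
            "hardness": (6.37, -0.018),
            "water_activity": (0.88, 0.0),
            "adhesiveness": (34.42, -0.146),
            "anthocyanins": (53.09, -0.117),
            "reducing_sugars": (30.0, 0.0),
            "soluble_solids": (37.0, 0.0),
        }),
        spec("FC", 0.6, 0.0, 0, (3.24, 3.26), (0.69, 0.70), _CONVENTIONAL_PROFILE, {
            "hardness": (6.80, 0.0),  # time-invariant: F below critical
            "water_activity": (0.73, -0.001),
            "adhesiveness": (68.41, -0.260),
            "anthocyanins": (39.25, -0.136),
            "reducing_sugars": (64.79, -0.083),
            "soluble_solids": (52.11, -0.009),
        }),
        spec("FD", 0.0, 1.2, 2, (3.42, 3.51), (0.40, 0.44), _LIGHT_PROFILE, {
            "hardness": (6.01, -0.011),
            "water_activity": (0.90, 0.0),
            "adhesiveness": (33.05, -0.104),
            "anthocyanins": (73.52, -0.251),
            "reducing_sugars": (30.0, 0.0),
            "soluble_solids": (37.0, 0.0),
        }),
    )


_ANALYTIC_DAYS = frozenset({0.0, 30.0, 90.0, 120.0})


def _trim_plan(specs, times, replicates, n_target):
    """Deterministic record trim: drop the highest replicate at the latest
    non-analytic times, round-robin over formulations, until the count
    matches.  Returns the set of (formulation, time, replicate) to drop."""
    full = len(specs) * len(times) * replicates
    excess = full - n_target
    if excess < 0:
        raise ValueError(
            f"grid yields {full} records, fewer than the requested {n_target}"
        )
    droppable_times = sorted(
        (t for t in times if float(t) not in _ANALYTIC_DAYS), reverse=True
    )
    drops = set()
    rep = replicates - 1
    k = 0
    while len(drops) < excess:
        if k >= len(droppable_times) * len(specs):
            k = 0
            rep -= 1
            if rep < 1:  # never drop below one replicate
                raise ValueError("cannot trim that many records")
        t = droppable_times[k // len(specs)]
        form = specs[k % len(specs)].id
        drops.add((form, float(t), rep))
        k += 1
    return drops


def generate_dataset(
    specs=None, cfg: GeneratorConfig = GeneratorConfig()
) -> pd.DataFrame:
    """Generate the jam storage record table.

    One row per formulation x time x replicate (after the deterministic
    trim to ``cfg.n_records``): covariates, component mass fractions and
    the six dependent properties, all drawn from ``cfg.seed``.
    """
    specs = tuple(specs) if specs is not None else default_specs()
    rng = np.random.default_rng(cfg.seed)
    drops = (
        _trim_plan(specs, cfg.times, cfg.replicates, cfg.n_records)
        if cfg.n_records is not None
        else set()
    )
    rows = []
    for sp in specs:
        for t in cfg.times:
            t = float(t)
            # batch-level covariates: shared by the replicates of one jar
            ph = rng.uniform(*sp.pH_range)
            ac = rng.uniform(*sp.acidity_range)
            comp = np.array([sp.composition[c] for c in sorted(sp.composition)])
            names = sorted(sp.composition)
            jitter = 1.0 + cfg.composition_jitter * rng.uniform(-1, 1, comp.size)
            comp = comp * jitter
            comp = comp / comp.sum()
            fractions = dict(zip(names, comp))
            for r in range(cfg.replicates):
                if (sp.id, t, r) in drops:
                    # still consume the noise stream so trimming, not the
                    # RNG layout, decides which records exist
                    rng.normal(size=len(PROPERTY_COLUMNS))
                    continue
                noise = rng.normal(size=len(PROPERTY_COLUMNS))
                row = {
                    "formulation": sp.id,
                    "time": t,
                    "replicate": r,
                    "HM": sp.pct_HM_pectin,
                    "LM": sp.pct_LM_pectin,
                    "xf": sp.pct_xanthan,
                    "pH": round(ph, 3),
                    "ac": round(ac, 3),
                }
                for c in names:
                    row[f"frac_{c}"] = fractions[c]
                for p, z in zip(PROPERTY_COLUMNS, noise):
                    row[p] = sp.mean(p, t) + sp.sigmas[p] * z
                rows.append(row)
    df = pd.DataFrame(rows)
    if cfg.n_records is not None and len(df) != cfg.n_records:
        raise AssertionError("trim plan failed to reach the target record count")
    return df


def write_records_csv(df: pd.DataFrame, path) -> None:
    """Write the record table in the tabular dialect
    (formulation, time, HM, LM, xf, pH, ac, fractions, properties)."""
    df.to_csv(path, index=False, float_format="%.6g")


def write_worksheet_bundle(
    df: pd.DataFrame,
    feature_columns,
    out_dir,
    split: SplitSpec,
) -> dict:
    """Write the six-worksheet layout as six CSV files.

    Worksheets 1/3/5 hold the independent variables of the learning,
    testing and prediction subsets; worksheets 2/4/6 the three dependent
    variables.  Returns a manifest (also written as JSON) with seeds,
    counts and file hashes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    idx = random_split(len(df), split)
    names = ("learning", "testing", "prediction")
    manifest = {"seed": split.seed, "counts": {}, "files": {}}
    for name, ids in zip(names, idx):
        sub = df.iloc[np.sort(ids)]
        for kind, cols in (("independent", list(feature_columns)),
                           ("dependent", list(RESPONSE_COLUMNS))):
            fname = f"{name}_{kind}.csv"
            fpath = out_dir / fname
            sub[cols].to_csv(fpath, index=False, float_format="%.6g")
            manifest["files"][fname] = hashlib.sha256(
                fpath.read_bytes()
            ).hexdigest()
        manifest["counts"][name] = len(sub)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def recovery_check(df: pd.DataFrame, specs=None) -> pd.DataFrame:
    """Refit every generated property series and compare with the truth.

    Fits replicate means per time with OLS and reports, per (formulation,
    property, coefficient), the estimate, the generating value and the
    z-score (estimate - truth) / standard error.
    """
    specs = {s.id: s for s in (specs if specs is not None else default_specs())}
    rows = []
    for (form, prop), sp in (
        (key, specs[key[0]]) for key in
        ((f, p) for f in specs for p in PROPERTY_COLUMNS)
    ):
        sub = df[df["formulation"] == form]
        means = sub.groupby("time")[prop].mean()
        x, y = means.index.to_numpy(), means.to_numpy()
        m = fit_linear(x, y)
        n = x.size
        resid = y - (m.intercept + m.slope * x)
        s2 = (resid**2).sum() / (n - 2)
        sxx = ((x - x.mean()) ** 2).sum()
        se_slope = np.sqrt(s2 / sxx)
        se_inter = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
        a_true, b_true = specs[form].models[prop]
        for coef, est, true, se in (
            ("intercept", m.intercept, a_true, se_inter),
            ("slope", m.slope, b_true, se_slope),
        ):
            rows.append(
                {
                    "formulation": form, "property": prop, "coefficient": coef,
                    "estimate": est, "truth": true, "stderr": se,
                    "z": (est - true) / se if se > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
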