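"""Configuration-driven orchestration of the full analysis.

One model per outcome x reporter x window combination: assemble the design,
build the requested exchangeability matrix, run the Gibbs sampler, summarize
exposure coefficients (posterior median and 95% CrI per pesticide), attach
convergence diagnostics, and write result tables plus a run manifest that
makes every output traceable to its configuration and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import date
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import catalog as cat
from .design import (
    PriorConfig,
    assemble_design,
    build_design_z,
    tau_from_half_width,
)
from .diagnostics import diagnostic_report
from .exposure import (
    ExposureConfig,
    ExposureWindow,
    Residence,
    SectionApplication,
    Station,
    WindRose,
    compute_exposure_matrix,
)
from .frequentist import fit_ml_mixed
from .sampler import MCMCConfig, run_mcmc, summarize
from .simulate import SimulationConfig, simulate_study

__all__ = [
    "RunManifest",
    "ConfigError",
    "run_study",
    "build_exposures_from_files",
    "load_tables",
]

logger = logging.getLogger(__name__)

Z_VARIANTS = ("primary", "class", "chemistry", "none")


class ConfigError(ValueError):
    pass


def _package_version() -> str:
    try:
        return pkg_version("pestmix")
    except PackageNotFoundError:
        return "unknown"


def _sha256_of(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str
    input_checksums: dict
    conventions: dict

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _parse_dates(df: pd.DataFrame, cols) -> pd.DataFrame:
    for c in cols:
        df[c] = pd.to_datetime(df[c]).dt.date
    return df


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigError(f"{name}: missing column(s) {missing}; found {list(df.columns)}")


def load_tables(indir) -> dict[str, pd.DataFrame]:
    """Read the raw exposure-build CSVs with schema validation."""
    indir = Path(indir)
    specs = {
        "residences": ["participant_id", "x", "y", "start_date", "end_date"],
        "applications": [
            "section_id", "centroid_x", "centroid_y", "date", "pesticide",
            "kilograms", "side_length",
        ],
        "wind": ["station_id", "date"] + [f"freq_{s.lower()}" for s in
                                          ("N", "NE", "E", "SE", "S", "SW", "W", "NW")],
        "stations": ["station_id", "x", "y"],
        "participants": ["participant_id", "birth_date"],
    }
    out = {}
    for name, cols in specs.items():
        path = indir / f"{name}.csv"
        if not path.exists():
            raise ConfigError(f"missing input file {path}")
        df = pd.read_csv(path)
        _require_columns(df, cols, name)
        out[name] = df
    return out


def build_exposures_from_files(
    indir,
    window_label: str,
    pesticides: Optional[list[str]] = None,
    config: ExposureConfig = ExposureConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Exposure matrix from CSV inputs; returns (long table, metadata)."""
    tables = load_tables(indir)
    res_df = _parse_dates(tables["residences"], ["start_date", "end_date"])
    app_df = _parse_dates(tables["applications"], ["date"])
    wind_df = _parse_dates(tables["wind"], ["date"])
    part_df = _parse_dates(tables["participants"], ["birth_date"])

    residences: dict[str, list[Residence]] = {}
    for r in res_df.itertuples():
        residences.setdefault(r.participant_id, []).append(
            Residence(r.participant_id, r.x, r.y, r.start_date, r.end_date)
        )
    apps = [
        SectionApplication(
            a.section_id, a.centroid_x, a.centroid_y, a.date, a.pesticide,
            a.kilograms, a.side_length,
        )
        for a in app_df.itertuples()
    ]
    stations = [Station(s.station_id, s.x, s.y) for s in tables["stations"].itertuples()]
    st_xy = {s.station_id: (s.x, s.y) for s in stations}
    freq_cols = [f"freq_{s.lower()}" for s in ("N", "NE", "E", "SE", "S", "SW", "W", "NW")]
    roses = [
        WindRose(w.station_id, *st_xy[w.station_id], w.date,
                 tuple(getattr(w, c) for c in freq_cols))
        for w in wind_df.itertuples()
    ]
    from .exposure import postnatal_window, prenatal_window

    maker = {"prenatal": prenatal_window, "postnatal": postnatal_window}[window_label]
    windows = [
        maker(p.participant_id, p.birth_date) for p in part_df.itertuples()
    ]
    if pesticides is None:
        pesticides = sorted({a.pesticide for a in apps})
    table = compute_exposure_matrix(residences, apps, roses, windows, pesticides,
                                    stations=stations, config=config)
    meta = config.metadata() | {"window": window_label, "pesticides": pesticides}
    return table, meta


def _derive_seed(master: int, index: int) -> int:
    return (master * 10_007 + 101 * index + 17) % (2**31)


def run_study(config: dict, outdir) -> dict:
    """Run every configured outcome x reporter x window model.

    ``config`` keys: seed; either ``simulate`` (SimulationConfig overrides)
    or ``inputs`` (paths to exposures/covariates/outcomes CSVs); ``window``;
    ``reporters``; ``outcomes`` (labels present in the outcome table);
    ``z_variant``; ``tau`` ({half_width, mass} or a number); ``mcmc``
    (MCMCConfig overrides); ``sex_interaction``; ``frequentist`` (also fit
    the ML comparator).  Returns {run label: summary table path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    window = config.get("window", "prenatal")
    z_variant = config.get("z_variant", "primary")
    if z_variant not in Z_VARIANTS:
        raise ConfigError(f"unknown z_variant {z_variant!r}; expected one of {Z_VARIANTS}")
    if window not in ("prenatal", "postnatal"):
        raise ConfigError(f"unknown window {window!r}")
    reporters = config.get("reporters", ["maternal"])
    sex_interaction = bool(config.get("sex_interaction", False))

    tau_cfg = config.get("tau", {"half_width": 5.0, "mass": 0.95})
    tau = float(tau_cfg) if np.isscalar(tau_cfg) else tau_from_half_width(
        tau_cfg.get("half_width", 5.0), tau_cfg.get("mass", 0.95)
    )
    priors = PriorConfig(tau=tau)

    checksums = {}
    if "inputs" in config:
        paths = {k: Path(v) for k, v in config["inputs"].items()}
        exposures = pd.read_csv(paths["exposures"])
        covariates = pd.read_csv(paths["covariates"])
        outcomes_df = pd.read_csv(paths["outcomes"])
        checksums = {k: _file_checksum(p) for k, p in paths.items()}
        outcome_labels = config.get("outcomes")
        if not outcome_labels:
            raise ConfigError("config key 'outcomes' (outcome column labels) is required")
    else:
        sim_over = dict(config.get("simulate", {}))
        sim_over.setdefault("seed", seed)
        sim_over.setdefault("window", window)
        sim = SimulationConfig(**sim_over)
        study = simulate_study(sim)
        study.write(outdir / "synthetic_inputs")
        exposures, covariates, outcomes_df = study.exposures, study.covariates, study.outcomes
        outcome_labels = config.get("outcomes", [sim.outcome_label])
        checksums = {"synthetic_seed": str(sim.seed)}

    for lbl in outcome_labels:
        if lbl not in outcomes_df.columns:
            raise ConfigError(
                f"outcome label {lbl!r} not in outcome table columns {list(outcomes_df.columns)}"
            )

    catalog = cat.default_catalog()
    available = set(exposures.loc[exposures["window"] == window, "pesticide"])
    pesticides = [p.name for p in catalog if p.name in available]
    if window == "prenatal":
        pesticides = [p for p in pesticides if p != "naled"]
    pre_adjust = None
    if window == "postnatal" and "prenatal" in set(exposures["window"]):
        pre_avail = set(exposures.loc[exposures["window"] == "prenatal", "pesticide"])
        pre_adjust = [p for p in cat.prenatal_pesticides() if p in pre_avail]

    mcmc_over = dict(config.get("mcmc", {}))
    results = {}
    run_index = 0
    for reporter in reporters:
        for outcome_label in outcome_labels:
            label = f"{outcome_label}_{reporter}_{window}"
            design = assemble_design(
                exposures, covariates, outcomes_df, window, reporter, outcome_label,
                pesticides, prenatal_adjustment=pre_adjust,
                sex_interaction=sex_interaction,
            )
            z = build_design_z(design.x_names, catalog, variant=z_variant)
            mcfg = MCMCConfig(**{"seed": _derive_seed(seed, run_index), **mcmc_over})
            chains = run_mcmc(design, z, priors, mcfg)
            run_index += 1

            betas = [f"beta[{p}]" for p in pesticides]
            summ = summarize(chains, params=betas)
            table = summ.table.copy()
            table["formatted"] = summ.formatted()
            path = outdir / f"summary_{label}.csv"
            table.to_csv(path)
            diagnostic_report(chains, params=betas).to_csv(outdir / f"diagnostics_{label}.csv")
            if config.get("frequentist", False):
                ml = fit_ml_mixed(design)
                ml.table.loc[betas].to_csv(outdir / f"ml_{label}.csv")
            results[label] = str(path)

    manifest = RunManifest(
        config_hash=_sha256_of(config),
        seed=seed,
        software_version=_package_version(),
        input_checksums=checksums,
        conventions={
            "z_variant": z_variant,
            "tau": tau,
            "window": window,
            "sex_interaction": sex_interaction,
            "credible_level": 0.95,
            "run_date": str(date.today()),
        },
    )
    manifest.write(outdir / "manifest.json")
    return results
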