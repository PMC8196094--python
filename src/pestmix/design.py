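"""First-stage design assembly and second-stage exchangeability structures.

The analysis regresses a behavioral T-score (mean 50, SD 10) on all pesticide
exposures simultaneously plus confounders, with a subject random intercept
across the two assessment visits:

    E[Y | X, W] = alpha + X beta + W gamma + u

and places a second-stage model on the exposure coefficients,

    beta = Z pi + delta,    delta ~ N(0, tau^2 I),

where Z maps each pesticide to the group(s) expected to act similarly
(chemical class, or ester chemistry plus potency).  Coefficients left out of
the hierarchy instead get a vague direct prior; a singleton group column
(beta = pi with vague pi) is equivalent to that and is implemented as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import PesticideInfo

__all__ = [
    "ZMatrix",
    "PriorConfig",
    "CovariateSchema",
    "DEFAULT_COVARIATE_SCHEMA",
    "StudyDesign",
    "tau_from_half_width",
    "build_primary_z",
    "build_class_z",
    "build_chemistry_z",
    "build_design_z",
    "assemble_design",
]

logger = logging.getLogger(__name__)


def tau_from_half_width(half_width: float, mass: float = 0.95) -> float:
    """Second-stage prior SD placing ``mass`` probability within ±half_width.

    The residual exposure effect delta is judged unlikely to move the
    outcome by more than half_width T-score units (the default ±5 is half
    an SD of the normative scale); tau is the SD of the mean-zero normal
    with that central probability mass.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if not 0 < mass < 1:
        raise ValueError("mass must lie strictly between 0 and 1")
    return half_width / stats.norm.ppf((1 + mass) / 2)


@dataclass
class PriorConfig:
    """Priors for the two-stage model.

    tau is the fixed second-stage residual SD; alpha, gamma and pi get
    mean-zero normal priors with ``vague_variance``; the residual and
    random-intercept variances get inverse-gamma(a0, b0) hyperpriors.
    """

    tau: float = field(default_factory=lambda: tau_from_half_width(5.0, 0.95))
    vague_variance: float = 1e6
    a0: float = 0.001
    b0: float = 0.001

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.vague_variance < 1e4:
            raise ValueError("vague_variance must be at least 1e4")


@dataclass
class ZMatrix:
    """Exchangeability design for the second stage.

    ``z`` has one row per exposure coefficient and one column per group;
    ``hierarchical`` flags rows that receive the N(Z pi, tau^2) prior.
    Non-hierarchical rows are all-zero in ``z`` and get a vague direct
    prior on beta.
    """

    z: pd.DataFrame
    hierarchical: pd.Series

    def __post_init__(self) -> None:
        if not self.z.index.equals(self.hierarchical.index):
            raise ValueError("z rows and hierarchical flags must align")
        hz = self.z.loc[self.hierarchical]
        if len(hz) and (np.abs(hz.to_numpy()).sum(axis=1) == 0).any():
            raise ValueError("every hierarchical coefficient needs a nonzero Z row")

    @property
    def coef_names(self) -> list[str]:
        return list(self.z.index)

    @property
    def n_hier(self) -> int:
        return int(self.hierarchical.sum())

    def hier_block(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(row mask, Z submatrix, group names) for the hierarchical rows."""
        mask = self.hierarchical.to_numpy(dtype=bool)
        hz = self.z.loc[self.hierarchical]
        cols = [c for c in hz.columns if np.abs(hz[c].to_numpy()).sum() > 0]
        return mask, hz[cols].to_numpy(dtype=float), cols


def _indicator_z(
    groups: dict[str, str], hierarchical_names: set[str], prefix: str = ""
) -> ZMatrix:
    names = list(groups)
    cols: list[str] = []
    for n in names:
        c = prefix + groups[n]
        if c not in cols:
            cols.append(c)
    z = pd.DataFrame(0.0, index=pd.Index(names, name="coef"), columns=cols)
    hier = pd.Series(False, index=z.index)
    for n in names:
        if n in hierarchical_names:
            z.loc[n, prefix + groups[n]] = 1.0
            hier.loc[n] = True
    return ZMatrix(z, hier)


def build_primary_z(
    pesticides: Sequence[PesticideInfo], coef_names: Optional[Sequence[str]] = None
) -> ZMatrix:
    """Primary exchangeability: pool only classes with more than one member.

    In practice only the organophosphates share a class, so they share one
    indicator column and borrow strength through a common class mean, while
    each remaining pesticide keeps a vague independent prior.
    """
    if not pesticides:
        raise ValueError("need at least one pesticide")
    names = list(coef_names) if coef_names is not None else [p.name for p in pesticides]
    class_of = {n: p.chem_class for n, p in zip(names, pesticides)}
    counts = pd.Series(list(class_of.values())).value_counts()
    pooled = {cls for cls, k in counts.items() if k > 1}
    groups = {n: (class_of[n] if class_of[n] in pooled else n) for n in names}
    hier = {n for n in names if class_of[n] in pooled}
    return _indicator_z(groups, hier)


def build_class_z(
    pesticides: Sequence[PesticideInfo], coef_names: Optional[Sequence[str]] = None
) -> ZMatrix:
    """Sensitivity exchangeability: one indicator column per chemical class,
    with every coefficient (singleton classes included) hierarchical."""
    if not pesticides:
        raise ValueError("need at least one pesticide")
    names = list(coef_names) if coef_names is not None else [p.name for p in pesticides]
    groups = {n: p.chem_class for n, p in zip(names, pesticides)}
    return _indicator_z(groups, set(names))


def build_chemistry_z(
    pesticides: Sequence[PesticideInfo],
    coef_names: Optional[Sequence[str]] = None,
    potency: str = "log_inverse",
) -> ZMatrix:
    """Ester-chemistry exchangeability for organophosphates.

    OP rows get a diethyl indicator, a dimethyl indicator, and a potency
    covariate from the benchmark dose (BMD10): "log_inverse" uses
    -log(BMD10), "inverse" uses 1/BMD10, "raw" uses BMD10, each standardized
    to mean 0, SD 1 across the OPs.  Non-OP pesticides keep vague priors.
    """
    if not pesticides:
        raise ValueError("need at least one pesticide")
    names = list(coef_names) if coef_names is not None else [p.name for p in pesticides]
    ops = [(n, p) for n, p in zip(names, pesticides) if p.chem_class == "organophosphate"]
    for n, p in ops:
        if p.bmd10 is None:
            raise ValueError(f"{n}: chemistry Z requires a benchmark dose for every OP")
    cols = ["diethyl", "dimethyl", "potency"]
    z = pd.DataFrame(0.0, index=pd.Index(names, name="coef"), columns=cols)
    hier = pd.Series(False, index=z.index)
    if ops:
        bmd = np.array([p.bmd10 for _, p in ops], dtype=float)
        if potency == "log_inverse":
            pot = -np.log(bmd)
        elif potency == "inverse":
            pot = 1.0 / bmd
        elif potency == "raw":
            pot = bmd.copy()
        else:
            raise ValueError("potency must be log_inverse, inverse or raw")
        sd = pot.std()
        pot = (pot - pot.mean()) / sd if sd > 0 else pot - pot.mean()
        for (n, p), v in zip(ops, pot):
            z.loc[n, p.op_subtype] = 1.0
            z.loc[n, "potency"] = v
            hier.loc[n] = True
    return ZMatrix(z, hier)


def _concat_z(parts: Sequence[ZMatrix]) -> ZMatrix:
    z = pd.concat([p.z for p in parts], axis=0).fillna(0.0)
    hier = pd.concat([p.hierarchical for p in parts])
    return ZMatrix(z, hier)


def build_design_z(
    x_names: Sequence[str],
    catalog: Sequence[PesticideInfo],
    variant: str = "primary",
    potency: str = "log_inverse",
) -> ZMatrix:
    """Exchangeability matrix for a full design's exposure columns.

    Column names of the design may carry a ``pre_`` prefix (prenatal
    adjustment exposures in postnatal models) or a ``:girl`` suffix
    (pesticide-by-sex interactions); pooling happens within each such block,
    with group columns prefixed by the block so e.g. the postnatal OP mean
    and the prenatal-adjustment OP mean are distinct second-stage
    parameters.  When interaction columns are present every coefficient is
    made hierarchical (class pooling), since all of them then benefit from
    shrinkage.
    """
    if variant not in ("primary", "class", "chemistry", "none"):
        raise ValueError(f"unknown Z variant {variant!r}")
    by_name = {p.name: p for p in catalog}

    blocks: dict[str, list[str]] = {}
    for name in x_names:
        if name.endswith(":girl"):
            blocks.setdefault("sex", []).append(name)
        elif name.startswith("pre_"):
            blocks.setdefault("pre", []).append(name)
        else:
            blocks.setdefault("main", []).append(name)

    has_interaction = "sex" in blocks
    parts = []
    for block in ("main", "pre", "sex"):
        if block not in blocks:
            continue
        coef_names = blocks[block]
        stripped = [n.removeprefix("pre_").removesuffix(":girl") for n in coef_names]
        pests = [by_name[s] for s in stripped]
        prefix = "" if block == "main" else block + ":"
        if variant == "none":
            z = pd.DataFrame(
                0.0, index=pd.Index(coef_names, name="coef"), columns=[prefix + "unused"]
            )
            parts.append(ZMatrix(z, pd.Series(False, index=z.index)))
            continue
        if variant == "chemistry":
            part = build_chemistry_z(pests, coef_names=coef_names, potency=potency)
            part.z.columns = [prefix + c for c in part.z.columns]
        elif variant == "class" or has_interaction:
            part = build_class_z(pests, coef_names=coef_names)
            part.z.columns = [prefix + c for c in part.z.columns]
        else:
            part = build_primary_z(pests, coef_names=coef_names)
            part.z.columns = [prefix + c for c in part.z.columns]
        parts.append(part)
    merged = _concat_z(parts)
    return ZMatrix(merged.z.loc[list(x_names)], merged.hierarchical.loc[list(x_names)])


# ---------------------------------------------------------------------------
# covariates


@dataclass(frozen=True)
class CovariateSchema:
    """Fixed confounder set; categoricals are reference-coded against the
    first listed level.  ``language_spanish`` enters maternal-report models
    only (youth assessments are all in English)."""

    continuous: tuple[str, ...] = ("maternal_age", "home_z")
    categorical: dict = field(
        default_factory=lambda: {
            "years_us": ("le5", "gt5_foreign", "us_born"),
            "education": ("le6", "grade7_12", "hs_grad"),
        }
    )
    binary: tuple[str, ...] = ("married", "depression", "sex_girl", "poverty")
    maternal_only_binary: tuple[str, ...] = ("language_spanish",)
    visit_level: tuple[str, ...] = ("age_at_visit",)

    def expand(self, covariates: pd.DataFrame, reporter: str) -> pd.DataFrame:
        """Reference-coded covariate matrix (participant-level columns)."""
        out = {}
        for c in self.continuous:
            out[c] = covariates[c].astype(float)
        for c, levels in self.categorical.items():
            col = covariates[c]
            unknown = set(col.dropna()) - set(levels)
            if unknown:
                raise ValueError(f"{c}: unknown level(s) {sorted(unknown)}")
            for level in levels[1:]:  # first level is the reference
                out[f"{c}[{level}]"] = (col == level).astype(float)
        binaries = self.binary + (self.maternal_only_binary if reporter == "maternal" else ())
        for c in binaries:
            out[c] = covariates[c].astype(float)
        return pd.DataFrame(out, index=covariates.index)


DEFAULT_COVARIATE_SCHEMA = CovariateSchema()


# ---------------------------------------------------------------------------
# design assembly


@dataclass
class StudyDesign:
    """Stacked two-visit design for one outcome x reporter x window model."""

    outcome_label: str
    window: str
    reporter: str
    y: np.ndarray  # may contain NaN (missing outcome at a visit)
    X: np.ndarray
    W: np.ndarray
    x_names: list[str]
    w_names: list[str]
    subject: np.ndarray  # 0-based subject codes per row
    subject_ids: list[str]
    sex_girl: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.y)
        for name, arr, width in (
            ("X", self.X, len(self.x_names)),
            ("W", self.W, len(self.w_names)),
        ):
            if arr.shape != (n, width):
                raise ValueError(f"{name} shape {arr.shape} misaligned with y/{name} names")
        if len(self.subject) != n or len(self.sex_girl) != n:
            raise ValueError("subject/sex vectors misaligned with y")
        counts = np.bincount(self.subject)
        if counts.max(initial=0) > 2:
            raise ValueError("a subject may contribute at most two visit rows")

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def _pivot_exposures(
    exposures: pd.DataFrame, window: str, pesticides: Sequence[str]
) -> pd.DataFrame:
    sub = exposures[exposures["window"] == window]
    wide = sub.pivot_table(
        index="participant_id", columns="pesticide", values="log2_use", aggfunc="first"
    )
    missing = [p for p in pesticides if p not in wide.columns]
    if missing:
        raise ValueError(f"no {window} exposure records for pesticide(s) {missing}")
    return wide[list(pesticides)]


def assemble_design(
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
    window: str,
    reporter: str,
    outcome_label: str,
    pesticides: Sequence[str],
    prenatal_adjustment: Optional[Sequence[str]] = None,
    sex_interaction: bool = False,
    schema: CovariateSchema = DEFAULT_COVARIATE_SCHEMA,
) -> StudyDesign:
    """Build the stacked first-stage design for one model.

    ``exposures`` is the long table (participant_id, window, pesticide,
    raw_kg, log2_use); ``covariates`` is participant-level with the schema's
    columns; ``outcomes`` has one row per participant x visit with columns
    participant_id, visit, age_at_visit, and the outcome column named
    ``outcome_label`` (NaN where that scale is missing).  Postnatal models
    pass ``prenatal_adjustment`` to append the prenatal exposure columns
    (prefixed ``pre_``) as structured adjustment covariates.  Participants
    with no observed outcome at either visit are excluded (count logged).
    """
    if window not in ("prenatal", "postnatal"):
        raise ValueError("window must be 'prenatal' or 'postnatal'")
    if reporter not in ("maternal", "youth"):
        raise ValueError("reporter must be 'maternal' or 'youth'")

    X_wide = _pivot_exposures(exposures, window, pesticides)
    if prenatal_adjustment:
        pre = _pivot_exposures(exposures, "prenatal", prenatal_adjustment)
        pre.columns = [f"pre_{c}" for c in pre.columns]
        X_wide = X_wide.join(pre, how="inner")

    cov = covariates.set_index("participant_id") if "participant_id" in covariates else covariates
    W_wide = schema.expand(cov, reporter)

    rows = outcomes[["participant_id", "visit", "age_at_visit", outcome_label]].copy()
    ids = [
        pid
        for pid in X_wide.index
        if pid in W_wide.index and pid in set(rows["participant_id"])
    ]
    rows = rows[rows["participant_id"].isin(ids)]

    observed_any = rows.groupby("participant_id")[outcome_label].apply(
        lambda s: s.notna().any()
    )
    dropped = int((~observed_any).sum())
    if dropped:
        logger.info(
            "%s/%s/%s: excluded %d participant(s) with no observed outcome",
            outcome_label,
            reporter,
            window,
            dropped,
        )
    keep = set(observed_any[observed_any].index)
    rows = rows[rows["participant_id"].isin(keep)].sort_values(["participant_id", "visit"])

    subject_ids = sorted(keep)
    code = {pid: i for i, pid in enumerate(subject_ids)}
    subject = rows["participant_id"].map(code).to_numpy(dtype=int)

    X = X_wide.loc[rows["participant_id"]].to_numpy(dtype=float)
    x_names = list(X_wide.columns)
    W_part = W_wide.loc[rows["participant_id"]].to_numpy(dtype=float)
    w_names = list(W_wide.columns) + list(schema.visit_level)
    W = np.column_stack([W_part, rows["age_at_visit"].to_numpy(dtype=float)])
    sex_girl = cov.loc[rows["participant_id"], "sex_girl"].to_numpy(dtype=float)

    if sex_interaction:
        inter = X[:, : len(pesticides)] * sex_girl[:, None]
        X = np.column_stack([X, inter])
        x_names = x_names + [f"{p}:girl" for p in pesticides]

    return StudyDesign(
        outcome_label=outcome_label,
        window=window,
        reporter=reporter,
        y=rows[outcome_label].to_numpy(dtype=float),
        X=X,
        W=W,
        x_names=x_names,
        w_names=w_names,
        subject=subject,
        subject_ids=subject_ids,
        sex_girl=sex_girl,
    )
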