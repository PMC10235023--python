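"""Synthetic multi-cohort matched case-control proteomics studies.

Generates 1:1 matched case-control studies that emulate the design of a
multi-cohort pre-diagnostic biomarker study: controls matched to cases on
cohort, sex, age (within one year) and a four-category smoking status;
proteins measured on panels with cohort-dependent availability (a full
library in some cohorts, a subset elsewhere); duplicate assays of the same
protein on two panels; values censored below a per-assay limit of detection
(LOD); lead time between blood draw and diagnosis of at most a few years.

Case labels are planted by the retrospective conditional-likelihood
mechanism: both members of a pair are drawn from a correlated bivariate
normal per protein, and the case label is assigned within the pair with
probability

    P(member 1 is the case) = exp(eta_1) / (exp(eta_1) + exp(eta_2)),

where ``eta_i = sum_j beta_j(L) * x_ij`` over planted proteins and
``beta_j(L) = beta0_j + beta_lead_j * L`` is the log odds ratio per SD at
lead time ``L``.  Under this mechanism the 1:1 conditional logistic model
holds exactly with the planted coefficients, so downstream estimators have a
known estimand without simulating a full source cohort.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ConfigurationError",
    "CohortSpec",
    "TruthTable",
    "SimConfig",
    "SimulatedStudy",
    "generate_study",
    "default_config",
]

HISTOLOGIES = ["adenocarcinoma", "squamous", "large_cell", "small_cell", "other"]
HISTOLOGY_PROBS = [0.34, 0.20, 0.04, 0.16, 0.26]

# TNM stage groups 1-4; marginals approximate a late-stage-dominated case mix.
STAGES = [1, 2, 3, 4]
STAGE_PROBS = [0.12, 0.11, 0.30, 0.47]
STAGE_MISSING_FRAC = 0.54

SMOKING_CATEGORIES = [
    "current_lt15",   # currently smoking, <15 cigarettes/day
    "current_ge15",   # currently smoking, >=15 cigarettes/day
    "former_lt10y",   # quit <10 years ago
    "former_ge10y",   # quit >=10 years ago
]
SMOKING_PROBS = [0.27, 0.27, 0.23, 0.23]


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: its name, number of matched sets, and measured panels."""

    name: str
    n_sets: int
    panels: tuple[str, ...]


@dataclass
class TruthTable:
    """Planted per-protein effects.

    ``table`` is indexed by protein id with columns

    beta0
        log odds ratio per SD at diagnosis (lead time 0).
    beta_lead
        linear change in the log OR per year of lead time.
    gamma_surv
        log hazard ratio per SD for post-diagnosis all-cause mortality.
    smoking_assoc
        linear loading of the protein on the smoking-exposure composite.

    ``histology_modifiers`` / ``smoking_modifiers`` optionally shift the log
    OR additively for sets whose case has the given histology, or whose pair
    has the given smoking-status category.  Null proteins carry all zeros.
    """

    table: pd.DataFrame
    histology_modifiers: dict[str, dict[str, float]] = field(default_factory=dict)
    smoking_modifiers: dict[str, dict[str, float]] = field(default_factory=dict)

    COLUMNS = ("beta0", "beta_lead", "gamma_surv", "smoking_assoc")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.table.columns:
                self.table[col] = 0.0
        self.table = self.table[list(self.COLUMNS)].astype(float)
        if not np.isfinite(self.table.to_numpy()).all():
            raise ConfigurationError("TruthTable contains non-finite entries")

    @classmethod
    def null(cls, proteins: list[str]) -> "TruthTable":
        """All-null truth for the given proteins."""
        return cls(pd.DataFrame(0.0, index=pd.Index(proteins, name="protein"), columns=list(cls.COLUMNS)))

    @classmethod
    def with_effects(cls, proteins: list[str], **per_protein: dict[str, float]) -> "TruthTable":
        """Null table overridden column-wise, e.g. ``beta0={"P0001": 0.5}``."""
        tt = cls.null(proteins)
        for col, mapping in per_protein.items():
            if col not in cls.COLUMNS:
                raise ConfigurationError(f"unknown truth column {col!r}")
            for prot, val in mapping.items():
                if prot not in tt.table.index:
                    raise ConfigurationError(f"planted protein {prot!r} not in protein list")
                tt.table.loc[prot, col] = float(val)
        return tt

    @property
    def planted(self) -> list[str]:
        """Proteins with any nonzero risk effect."""
        nz = (self.table[["beta0", "beta_lead"]] != 0).any(axis=1)
        return list(self.table.index[nz])


@dataclass
class SimConfig:
    """Full description of one synthetic study.

    Defaults mirror the target design: six cohorts, two of which measure the
    full panel library; 1:1 matching on cohort, sex, age (+-1y) and smoking
    status in four categories; lead time uniform on [0, 3] years; a small
    fraction of proteins duplicated on a second panel; per-assay LOD at the
    pooled 5th percentile.
    """

    cohorts: list[CohortSpec]
    n_proteins: int
    panel_map: dict[str, str] | None = None
    duplicate_fraction: float = 0.1
    truth: TruthTable | None = None
    within_pair_corr: float = 0.2
    lod_quantile: float = 0.05
    lead_time_max_years: float = 3.0
    survival_params: dict[str, float] = field(
        default_factory=lambda: {"baseline_scale": 4.0, "censor_scale": 8.0}
    )
    seed: int = 0

    def proteins(self) -> list[str]:
        return [f"P{i + 1:04d}" for i in range(self.n_proteins)]

    def resolved_panel_map(self) -> dict[str, str]:
        if self.panel_map is not None:
            return dict(self.panel_map)
        panels = sorted({p for c in self.cohorts for p in c.panels})
        if not panels:
            raise ConfigurationError("no panels configured")
        return {prot: panels[i % len(panels)] for i, prot in enumerate(self.proteins())}

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if not self.cohorts:
            raise ConfigurationError("at least one cohort required")
        for c in self.cohorts:
            if c.n_sets < 1:
                raise ConfigurationError(f"cohort {c.name}: n_sets must be >= 1")
            if not c.panels:
                raise ConfigurationError(f"cohort {c.name}: measures no panels")
        if not 0.0 <= self.lod_quantile <= 0.5:
            raise ConfigurationError("lod_quantile must lie in [0, 0.5]")
        if not 0.0 <= self.within_pair_corr < 1.0:
            raise ConfigurationError("within_pair_corr must lie in [0, 1)")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ConfigurationError("duplicate_fraction must lie in [0, 1]")
        pmap = self.resolved_panel_map()
        missing = set(self.proteins()) - set(pmap)
        if missing:
            raise ConfigurationError(f"proteins without a panel assignment: {sorted(missing)[:5]}")
        all_panels = {p for c in self.cohorts for p in c.panels}
        orphan = set(pmap.values()) - all_panels
        if orphan:
            raise ConfigurationError(f"panels not measured by any cohort: {sorted(orphan)}")
        if self.truth is not None:
            unknown = set(self.truth.table.index) - set(self.proteins())
            if unknown:
                raise ConfigurationError(f"truth refers to unknown proteins: {sorted(unknown)[:5]}")


@dataclass
class SimulatedStudy:
    """A generated study: metadata, raw matrix, LOD mask, annotations, truth.

    ``matrix`` holds raw NPX-like (log2-scale) values, one column per assay;
    entries are NaN where the sample's cohort did not measure the assay's
    panel.  ``lod_mask`` is True where a measured value fell below the
    assay's LOD (the raw value is retained; substitution is a preprocessing
    step).  ``annotations`` has one row per assay: protein, panel, lod, and
    the measuring cohorts.
    """

    subjects: pd.DataFrame
    matrix: pd.DataFrame
    lod_mask: pd.DataFrame
    annotations: pd.DataFrame
    truth: TruthTable
    config: SimConfig

    @property
    def n_sets(self) -> int:
        return self.subjects["set_id"].nunique()

    def cases(self) -> pd.DataFrame:
        return self.subjects[self.subjects["case"] == 1]


def _smoking_composite(cigs: np.ndarray, years: np.ndarray, ysc: np.ndarray) -> np.ndarray:
    """Roughly standardized smoking-exposure composite used for planted
    protein-smoking associations and the baseline risk score."""
    return ((cigs - 18.0) / 12.0 + (years - 37.0) / 13.0 - (ysc - 8.0) / 12.0) / np.sqrt(3.0)


def _draw_smoking(rng: np.random.Generator, cat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(cat)
    cigs = np.empty(n)
    ysc = np.zeros(n)
    current_lt = cat == "current_lt15"
    current_ge = cat == "current_ge15"
    former_lt = cat == "former_lt10y"
    former_ge = cat == "former_ge10y"
    cigs[current_lt] = rng.uniform(4, 15, current_lt.sum())
    cigs[current_ge] = rng.uniform(15, 45, current_ge.sum())
    cigs[former_lt | former_ge] = rng.uniform(4, 45, (former_lt | former_ge).sum())
    years = np.clip(rng.normal(38, 10, n), 8, 62)
    ysc[former_lt] = rng.uniform(0, 10, former_lt.sum())
    ysc[former_ge] = rng.uniform(10, 32, former_ge.sum())
    return cigs, years, ysc


def generate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a matched study; a pure function of ``config`` (incl. seed).

    Every matched set has exactly one case and one control from the same
    cohort with identical sex and smoking category and ages within one year,
    and the case label satisfies the conditional-logistic model with the
    planted coefficients exactly (see module docstring).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    proteins = config.proteins()
    pmap = config.resolved_panel_map()
    truth = config.truth if config.truth is not None else TruthTable.null(proteins)
    # align truth to full protein list (unlisted proteins are null)
    tt = truth.table.reindex(proteins).fillna(0.0)

    # assays: primary per protein + noisy duplicates on another panel
    panels = sorted({p for c in config.cohorts for p in c.panels})
    n_dup = int(round(config.duplicate_fraction * config.n_proteins))
    dup_proteins = list(rng.choice(proteins, size=n_dup, replace=False)) if n_dup else []
    assay_rows = []
    for prot in proteins:
        assay_rows.append({"assay": prot, "protein": prot, "panel": pmap[prot]})
    for prot in dup_proteins:
        others = [p for p in panels if p != pmap[prot]] or [pmap[prot]]
        dup_panel = others[hash_stable(prot) % len(others)]
        assay_rows.append({"assay": f"{prot}__dup", "protein": prot, "panel": dup_panel})
    annotations = pd.DataFrame(assay_rows).set_index("assay")

    beta0 = tt["beta0"].to_numpy()
    beta_lead = tt["beta_lead"].to_numpy()
    gamma = tt["gamma_surv"].to_numpy()
    smk_load = tt["smoking_assoc"].to_numpy()
    rho = config.within_pair_corr

    mu = rng.uniform(5.0, 10.0, len(annotations))
    sigma = rng.uniform(0.5, 1.5, len(annotations))

    subj_frames: list[pd.DataFrame] = []
    value_blocks: list[np.ndarray] = []
    for cohort in config.cohorts:
        n = cohort.n_sets
        set_ids = [f"{cohort.name}_{i + 1:05d}" for i in range(n)]
        lead = rng.uniform(0.0, config.lead_time_max_years, n)
        age1 = rng.normal(65.0, 9.0, n)
        age2 = age1 + rng.uniform(-1.0, 1.0, n)
        female = rng.random(n) < 0.33
        smoke_cat = rng.choice(SMOKING_CATEGORIES, size=n, p=SMOKING_PROBS)
        histology = rng.choice(HISTOLOGIES, size=n, p=HISTOLOGY_PROBS)
        stage = rng.choice(STAGES, size=n, p=STAGE_PROBS).astype(float)
        stage[rng.random(n) < STAGE_MISSING_FRAC] = np.nan

        cigs1, years1, ysc1 = _draw_smoking(rng, smoke_cat)
        cigs2, years2, ysc2 = _draw_smoking(rng, smoke_cat)
        s1 = _smoking_composite(cigs1, years1, ysc1)
        s2 = _smoking_composite(cigs2, years2, ysc2)

        # latent standardized protein values: within-pair correlation rho
        shared = rng.standard_normal((n, config.n_proteins))
        e1 = rng.standard_normal((n, config.n_proteins))
        e2 = rng.standard_normal((n, config.n_proteins))
        x1 = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * e1 + np.outer(s1, smk_load)
        x2 = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * e2 + np.outer(s2, smk_load)

        # effective log OR per SD for each set x protein
        beta_eff = beta0[None, :] + np.outer(lead, beta_lead)
        for prot, mods in truth.histology_modifiers.items():
            j = proteins.index(prot)
            beta_eff[:, j] += np.array([mods.get(h, 0.0) for h in histology])
        for prot, mods in truth.smoking_modifiers.items():
            j = proteins.index(prot)
            beta_eff[:, j] += np.array([mods.get(c, 0.0) for c in smoke_cat])

        eta1 = (beta_eff * x1).sum(axis=1)
        eta2 = (beta_eff * x2).sum(axis=1)
        member1_is_case = rng.random(n) < expit(eta1 - eta2)

        x_case = np.where(member1_is_case[:, None], x1, x2)
        lin_surv = x_case @ gamma
        base = config.survival_params.get("baseline_scale", 4.0)
        cens = config.survival_params.get("censor_scale", 8.0)
        t_death = rng.exponential(base * np.exp(-lin_surv))
        t_cens = rng.exponential(cens, n)
        surv_time = np.minimum(t_death, t_cens)
        death = (t_death <= t_cens).astype(int)

        def member_frame(which: int, is_case: np.ndarray) -> pd.DataFrame:
            cigs, years, ysc = (cigs1, years1, ysc1) if which == 1 else (cigs2, years2, ysc2)
            age = age1 if which == 1 else age2
            score = 0.03 * cigs + 0.02 * years - 0.015 * ysc + rng.normal(0, 0.8, n)
            return pd.DataFrame(
                {
                    "sample_id": [f"{sid}_{'a' if which == 1 else 'b'}" for sid in set_ids],
                    "set_id": set_ids,
                    "cohort": cohort.name,
                    "case": is_case.astype(int),
                    "age": age,
                    "sex": np.where(female, "F", "M"),
                    "smoking_status": smoke_cat,
                    "cigs_per_day": cigs,
                    "years_smoked": years,
                    "years_since_cessation": ysc,
                    "lead_time": np.where(is_case, lead, np.nan),
                    "histology": np.where(is_case, histology, None),
                    "stage": np.where(is_case, stage, np.nan),
                    "surv_time": np.where(is_case, surv_time, np.nan),
                    "death": np.where(is_case, death, 0),
                    "baseline_score": score,
                }
            )

        subj_frames.append(member_frame(1, member1_is_case))
        subj_frames.append(member_frame(2, ~member1_is_case))

        # raw NPX-like values per assay; NaN where the cohort lacks the panel
        lat = np.vstack([x1, x2])  # member-1 rows then member-2 rows
        cols = []
        for k, (assay, row) in enumerate(annotations.iterrows()):
            j = proteins.index(row["protein"])
            v = mu[k] + sigma[k] * lat[:, j]
            if assay.endswith("__dup"):
                v = v + rng.normal(0.0, 0.2 * sigma[k], len(v))
            if row["panel"] not in cohort.panels:
                v = np.full(len(v), np.nan)
            cols.append(v)
        value_blocks.append(np.column_stack(cols))

    subjects = pd.concat(subj_frames, ignore_index=True)
    # interleave member-1/member-2 rows back into cohort order
    order = np.argsort(subjects["sample_id"].to_numpy(), kind="stable")
    subjects = subjects.iloc[order].reset_index(drop=True)

    values = np.vstack(value_blocks)
    sample_ids = []
    for cohort, frame in zip(config.cohorts, subj_frames[::2]):
        sids = frame["set_id"]
        sample_ids.extend([f"{s}_a" for s in sids])
        sample_ids.extend([f"{s}_b" for s in sids])
    matrix = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=annotations.index)
    matrix = matrix.sort_index()
    subjects = subjects.set_index("sample_id").loc[matrix.index].reset_index()

    # per-assay LOD at the pooled quantile of measured values
    lods = matrix.quantile(config.lod_quantile)
    annotations["lod"] = lods
    lod_mask = matrix.lt(lods, axis=1) & matrix.notna()

    annotations["cohorts"] = [
        ";".join(c.name for c in config.cohorts if panel in c.panels)
        for panel in annotations["panel"]
    ]

    return SimulatedStudy(
        subjects=subjects,
        matrix=matrix,
        lod_mask=lod_mask,
        annotations=annotations,
        truth=TruthTable(tt.copy(), truth.histology_modifiers, truth.smoking_modifiers),
        config=config,
    )


def hash_stable(text: str) -> int:
    """Stable non-negative integer hash (process-independent)."""
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


def default_config(
    n_proteins: int = 60,
    scale: float = 1.0,
    truth: TruthTable | None = None,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """Six-cohort layout mirroring the target design.

    Two cohorts (EPIC-like, NSHDS-like) measure the full panel library; the
    remaining four measure a subset of panels.  ``scale`` multiplies the
    per-cohort set counts (1.0 reproduces the 731-set design).
    """
    full = ("panel1", "panel2", "panel3", "panel4")
    subset = ("panel1", "panel2")
    sizes = {"EPIC": 188, "NSHDS": 64, "HUNT": 164, "CPS2": 115, "MCCS": 108, "SCHS": 92}
    cohorts = [
        CohortSpec(name, max(1, int(round(n * scale))), full if name in ("EPIC", "NSHDS") else subset)
        for name, n in sizes.items()
    ]
    cfg = SimConfig(cohorts=cohorts, n_proteins=n_proteins, truth=truth, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
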