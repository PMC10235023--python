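"""Resampling discovery-replication selection of replicable risk proteins.

The algorithm simulates many split-sample discovery/replication analyses:
in each of ``n_iter`` iterations the matched sets are split 70/30 into
discovery and replication sets, balanced by cohort (sets, never
individuals, are split; designated cohorts can be forced wholly into
discovery).  Per protein and iteration, a conditional logistic model is fit
on each side; the protein passes the iteration if its discovery p-value is
below ``0.05 / ENT`` (effective number of tests) and its replication
p-value is below 0.05 (optionally also requiring the two coefficient signs
to agree).  Proteins passing at least half (configurable) of the iterations
are selected.

A single split-sample variant — discovery fixed to designated cohorts,
BH-FDR < 0.05 in discovery, p < 0.05 in replication — is provided as the
sensitivity comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import case_control_differences, fit_clogit_many
from .multiplicity import ENTResult, bh_fdr, effective_number_of_tests

__all__ = [
    "ResamplingConfig",
    "SelectionResult",
    "resample_select",
    "single_split_select",
    "compare_selections",
]


@dataclass
class ResamplingConfig:
    n_iter: int = 500
    discovery_fraction: float = 0.7
    forced_discovery_cohorts: tuple[str, ...] = ()
    selection_frequency: float = 0.5
    require_sign_concordance: bool = True
    min_sets_per_side: int = 25
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.discovery_fraction < 1.0:
            raise ValueError("discovery_fraction must lie in (0, 1)")
        if not 0.0 <= self.selection_frequency <= 1.0:
            raise ValueError("selection_frequency must lie in [0, 1]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class SelectionResult:
    """Per-protein pass frequencies and the selected flag.

    ``table`` columns: discovery_pass_freq, replication_pass_freq,
    joint_pass_freq, n_pass, n_iter, selected.  ``iteration_log`` records,
    per iteration, the discovery cohort composition so forced-cohort and
    set-integrity invariants can be audited.
    """

    table: pd.DataFrame
    ent: ENTResult | None
    method: str
    config: ResamplingConfig | None = None
    iteration_log: list[dict] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def _banker_round(x: float) -> int:
    return int(np.rint(x))


def _split_sets(
    rng: np.random.Generator,
    sets_by_cohort: dict[str, np.ndarray],
    discovery_fraction: float,
    forced: set[str],
) -> tuple[np.ndarray, np.ndarray]:
    disc, repl = [], []
    for cohort, sets in sets_by_cohort.items():
        if cohort in forced:
            disc.append(sets)
            continue
        perm = rng.permutation(sets)
        n_disc = _banker_round(discovery_fraction * len(sets))
        disc.append(perm[:n_disc])
        repl.append(perm[n_disc:])
    disc_all = np.concatenate(disc) if disc else np.array([], dtype=object)
    repl_all = np.concatenate(repl) if repl else np.array([], dtype=object)
    return disc_all, repl_all


def resample_select(
    matrix: pd.DataFrame,
    subjects: pd.DataFrame,
    protein_set: list[str] | None = None,
    config: ResamplingConfig | None = None,
) -> SelectionResult:
    """Run the resampling discovery-replication algorithm.

    ``matrix`` is the preprocessed (standardized) samples-by-protein frame;
    proteins not measured in a cohort are NaN there and are evaluated only
    on sets with complete values (a protein enters an iteration only if at
    least ``min_sets_per_side`` complete sets fall on each side).  ENT is
    computed once on the full matrix of the protein set in play.  The whole
    run is a pure function of the data and the config seed.
    """
    config = config or ResamplingConfig()
    config.validate()
    proteins = list(protein_set) if protein_set is not None else list(matrix.columns)
    sub = matrix[proteins]

    cohort_of_set = subjects.groupby("set_id")["cohort"].first()
    forced = set(config.forced_discovery_cohorts)
    unknown = forced - set(cohort_of_set.unique())
    if unknown:
        raise ValueError(f"forced cohorts not present in study: {sorted(unknown)}")
    if forced >= set(cohort_of_set.unique()):
        raise ValueError("all cohorts forced into discovery: replication side empty")

    ent = effective_number_of_tests(sub)
    thresh_disc = 0.05 / ent.ent

    diffs = case_control_differences(sub, subjects)
    sets_by_cohort = {
        c: ids.to_numpy() for c, ids in cohort_of_set.groupby(cohort_of_set).groups.items()
    }
    set_index = pd.Index(diffs.index)

    rng = np.random.default_rng(config.seed)
    P = len(proteins)
    n_pass = np.zeros(P, dtype=int)
    n_disc_pass = np.zeros(P, dtype=int)
    n_repl_pass = np.zeros(P, dtype=int)
    log: list[dict] = []
    for it in range(config.n_iter):
        disc_ids, repl_ids = _split_sets(rng, sets_by_cohort, config.discovery_fraction, forced)
        Dd = diffs.loc[set_index.intersection(disc_ids, sort=False)]
        Dr = diffs.loc[set_index.intersection(repl_ids, sort=False)]
        fd = fit_clogit_many(Dd, min_sets=config.min_sets_per_side)
        fr = fit_clogit_many(Dr, min_sets=config.min_sets_per_side)
        eligible = (fd["n_sets"].to_numpy() >= config.min_sets_per_side) & (
            fr["n_sets"].to_numpy() >= config.min_sets_per_side
        )
        pd_ok = (fd["p"].to_numpy() < thresh_disc) & eligible
        pr_ok = (fr["p"].to_numpy() < 0.05) & eligible
        joint = pd_ok & pr_ok
        if config.require_sign_concordance:
            joint &= np.sign(fd["beta"].to_numpy()) == np.sign(fr["beta"].to_numpy())
        n_disc_pass += np.where(np.isnan(fd["p"].to_numpy()), False, pd_ok)
        n_repl_pass += np.where(np.isnan(fr["p"].to_numpy()), False, pr_ok)
        n_pass += np.where(np.isnan(fd["p"].to_numpy()) | np.isnan(fr["p"].to_numpy()), False, joint)
        log.append(
            {
                "iteration": it,
                "n_discovery_sets": len(Dd),
                "n_replication_sets": len(Dr),
                "discovery_cohorts": sorted(set(cohort_of_set.loc[Dd.index])),
                "replication_cohorts": sorted(set(cohort_of_set.loc[Dr.index])),
            }
        )

    freq = n_pass / config.n_iter
    table = pd.DataFrame(
        {
            "discovery_pass_freq": n_disc_pass / config.n_iter,
            "replication_pass_freq": n_repl_pass / config.n_iter,
            "joint_pass_freq": freq,
            "n_pass": n_pass,
            "n_iter": config.n_iter,
            "selected": (freq >= config.selection_frequency) & (n_pass > 0),
        },
        index=pd.Index(proteins, name="protein"),
    )
    return SelectionResult(table=table, ent=ent, method="resampling", config=config, iteration_log=log)


def single_split_select(
    matrix: pd.DataFrame,
    subjects: pd.DataFrame,
    discovery_cohorts: tuple[str, ...],
    protein_set: list[str] | None = None,
    min_sets_per_side: int = 25,
    require_sign_concordance: bool = True,
) -> SelectionResult:
    """Single fixed split by cohort membership: BH-FDR < 0.05 in discovery
    and p < 0.05 in replication."""
    proteins = list(protein_set) if protein_set is not None else list(matrix.columns)
    sub = matrix[proteins]
    cohort_of_set = subjects.groupby("set_id")["cohort"].first()
    known = set(cohort_of_set.unique())
    unknown = set(discovery_cohorts) - known
    if unknown:
        raise ValueError(f"discovery cohorts not present: {sorted(unknown)}")
    repl_cohorts = known - set(discovery_cohorts)
    if not repl_cohorts:
        raise ValueError("empty replication: every cohort assigned to discovery")

    diffs = case_control_differences(sub, subjects)
    in_disc = cohort_of_set.loc[diffs.index].isin(discovery_cohorts).to_numpy()
    fd = fit_clogit_many(diffs.loc[in_disc], min_sets=min_sets_per_side)
    fr = fit_clogit_many(diffs.loc[~in_disc], min_sets=min_sets_per_side)
    eligible = (fd["n_sets"].to_numpy() >= min_sets_per_side) & (
        fr["n_sets"].to_numpy() >= min_sets_per_side
    )
    q = bh_fdr(fd["p"].to_numpy())
    sel = eligible & (q < 0.05) & (fr["p"].to_numpy() < 0.05)
    if require_sign_concordance:
        sel &= np.sign(fd["beta"].to_numpy()) == np.sign(fr["beta"].to_numpy())
    sel = np.where(np.isnan(q) | np.isnan(fr["p"].to_numpy()), False, sel).astype(bool)
    table = pd.DataFrame(
        {
            "discovery_p": fd["p"].to_numpy(),
            "discovery_q": q,
            "replication_p": fr["p"].to_numpy(),
            "discovery_beta": fd["beta"].to_numpy(),
            "replication_beta": fr["beta"].to_numpy(),
            "selected": sel,
        },
        index=pd.Index(proteins, name="protein"),
    )
    return SelectionResult(table=table, ent=None, method="single-split")


def compare_selections(a: SelectionResult, b: SelectionResult) -> dict:
    """Overlap summary of two selection runs on the same protein universe."""
    ua, ub = set(a.table.index), set(b.table.index)
    if ua != ub:
        raise ValueError("selection results cover different protein universes")
    sa, sb = set(a.selected), set(b.selected)
    concordance = pd.DataFrame(
        {
            "selected_a": [p in sa for p in sorted(ua)],
            "selected_b": [p in sb for p in sorted(ua)],
        },
        index=pd.Index(sorted(ua), name="protein"),
    )
    return {
        "both": len(sa & sb),
        "only_a": len(sa - sb),
        "only_b": len(sb - sa),
        "neither": len(ua - sa - sb),
        "table": concordance,
    }
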