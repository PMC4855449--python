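"""Desk-scale experiments on synthetic cohorts.

Three experiments probe the behaviors that decide whether a three-ancestry
maximum-likelihood panel is trustworthy:

* :func:`se_curve` — how the information-matrix standard error of the
  ancestry estimates falls as markers are added (roughly as 1/sqrt(G));
* :func:`vertex_recovery_experiment` — estimating pure-ancestry cohorts with
  each single maximized-contrast set and with the full panel, exposing the
  unbalanced-panel failure: when a cohort's ancestry is absent from the
  maximized contrast, the estimates drift far from 1.0 with inflated SD;
* :func:`replicate_concordance_experiment` — how closely two disjoint
  balanced panels agree on the same individuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .aims import balance_report
from .errors import ValidationError
from .mle import estimate_cohort
from .panel_io import SET_LABELS, GenotypeMatrix, ParentalPanel
from .simulate import CohortTruth, simulate_cohort

logger = logging.getLogger(__name__)

_VERTICES = {"EU": (1.0, 0.0, 0.0), "AI": (0.0, 1.0, 0.0), "AF": (0.0, 0.0, 1.0)}


def subset_genotypes(geno: GenotypeMatrix, idx: np.ndarray) -> GenotypeMatrix:
    """Genotype matrix restricted to the panel SNPs at positional indices ``idx``.

    The subset panel is re-sorted to genome order and the dosage columns are
    permuted to match (estimates are invariant to SNP order).
    """
    idx = np.asarray(idx)
    sub_df = geno.panel.df.iloc[idx].reset_index(drop=True)
    sub_panel = ParentalPanel(sub_df)
    order = pd.Index(sub_panel.snp_ids).get_indexer(geno.panel.snp_ids[idx])
    # order maps panel-sorted position -> position within idx
    inv = np.empty(len(idx), dtype=int)
    inv[order] = np.arange(len(idx))
    return GenotypeMatrix(geno.sample_ids, geno.dosages[:, idx][:, inv], sub_panel)


def _set_interleaved_order(panel: ParentalPanel, rng: np.random.Generator) -> np.ndarray:
    """Indices interleaving the three maximized sets round-robin, each set's
    internal order randomized; panels without set labels are simply shuffled."""
    labels = panel.set_labels
    if labels is None:
        order = np.arange(panel.G)
        rng.shuffle(order)
        return order
    queues = []
    for label in SET_LABELS:
        q = np.flatnonzero(labels == label)
        rng.shuffle(q)
        queues.append(list(q))
    order = []
    while any(queues):
        for q in queues:
            if q:
                order.append(q.pop())
    return np.array(order)


@dataclass
class SECurve:
    """Mean standard error of the ancestry estimates vs. number of markers."""

    table: pd.DataFrame = field(repr=False)  # n_snps, mean_se, mean_se_{eu,ai,af}
    ordering: str = "randomized-interleaved"

    @property
    def snp_counts(self) -> np.ndarray:
        return self.table["n_snps"].to_numpy()

    @property
    def mean_se(self) -> np.ndarray:
        return self.table["mean_se"].to_numpy()

    def se_at(self, n_snps: int) -> float:
        row = self.table[self.table["n_snps"] == n_snps]
        if row.empty:
            raise KeyError(f"no curve point at {n_snps} SNPs")
        return float(row["mean_se"].iloc[0])


def se_curve(
    truth: CohortTruth,
    panel: ParentalPanel,
    snp_counts: Sequence[int] | None = None,
    ordering: Literal["randomized-interleaved", "chromosome-position"] = "randomized-interleaved",
    seed: int | None = None,
    missing_rate: float = 0.0,
    thin: int = 10,
    grid_step: float = 0.001,
) -> SECurve:
    """Standard error of the ancestry estimates as markers accumulate.

    A cohort is simulated from ``truth`` on the full panel; for each marker
    count the estimator runs on that prefix of the chosen ordering, and the
    information-matrix SEs are averaged over individuals (groups weighted
    equally) and over the three ancestry components.  ``snp_counts`` defaults
    to every ``thin``-th count up to G, always including G.
    """
    rng = np.random.default_rng(seed)
    if panel.set_labels is not None:
        rep = balance_report(panel)
        if not rep.balanced:
            warnings.warn(
                "panel is unbalanced across contrasts; the SE curve will reflect "
                "the failure mode rather than the calibrated decay", stacklevel=2,
            )
    if snp_counts is None:
        snp_counts = sorted(set(range(thin, panel.G + 1, thin)) | {panel.G})
    snp_counts = sorted(int(c) for c in snp_counts)
    if snp_counts[0] < 1 or snp_counts[-1] > panel.G:
        raise ValidationError("snp_counts must lie in [1, G]")

    if ordering == "chromosome-position":
        order = np.arange(panel.G)
    elif ordering == "randomized-interleaved":
        order = _set_interleaved_order(panel, rng)
    else:
        raise ValueError(f"unknown ordering {ordering!r}")

    geno = simulate_cohort(panel, truth, missing_rate=missing_rate,
                           seed=int(rng.integers(2**31)))
    groups = np.asarray(truth.group)
    rows = []
    for count in snp_counts:
        sub = subset_genotypes(geno, order[:count])
        ests = estimate_cohort(sub, grid_step=grid_step, on_degenerate="nan")
        ses = np.array([e.standard_errors for e in ests])  # (n, 3)
        per_group = [np.nanmean(ses[groups == g], axis=0) for g in np.unique(groups)]
        comp_means = np.mean(per_group, axis=0)
        rows.append(
            {
                "n_snps": count,
                "mean_se": float(np.mean(comp_means)),
                "mean_se_eu": float(comp_means[0]),
                "mean_se_ai": float(comp_means[1]),
                "mean_se_af": float(comp_means[2]),
                "n_degenerate": int(np.isnan(ses).any(axis=1).sum()),
            }
        )
    return SECurve(table=pd.DataFrame(rows), ordering=ordering)


def vertex_recovery_experiment(
    panel: ParentalPanel,
    n_per_population: int = 100,
    seed: int | None = None,
    grid_step: float = 0.001,
) -> pd.DataFrame:
    """Estimate pure-ancestry cohorts with each maximized set and the full panel.

    Simulates a cohort at each simplex vertex (pure EU, AI, AF) and estimates
    it four times: once per single maximized-contrast set and once with all
    SNPs.  Returns a table with mean and SD of each estimated component; the
    expectation for a balanced marker set is a mean near 1.0 for the cohort's
    own component, and the signature failure is an unstable, off-1.0 mean
    with inflated SD when the cohort's ancestry is not in the maximized
    contrast.
    """
    labels = panel.set_labels
    if labels is None:
        raise ValidationError("vertex_recovery_experiment needs a set-labeled panel")
    rng = np.random.default_rng(seed)
    cohorts = {}
    for pop, vertex in _VERTICES.items():
        truth = CohortTruth(np.tile(vertex, (n_per_population, 1)),
                            group=[pop] * n_per_population)
        cohorts[pop] = simulate_cohort(panel, truth, seed=int(rng.integers(2**31)))

    rows = []
    for snp_set in list(SET_LABELS) + ["all"]:
        idx = np.arange(panel.G) if snp_set == "all" else np.flatnonzero(labels == snp_set)
        for pop, geno in cohorts.items():
            ests = estimate_cohort(subset_genotypes(geno, idx), grid_step=grid_step,
                                   on_degenerate="nan")
            props = np.array([e.proportions for e in ests])
            rows.append(
                {
                    "snp_set": snp_set,
                    "n_snps": len(idx),
                    "source": pop,
                    "mean_eu": props[:, 0].mean(), "sd_eu": props[:, 0].std(ddof=1),
                    "mean_ai": props[:, 1].mean(), "sd_ai": props[:, 1].std(ddof=1),
                    "mean_af": props[:, 2].mean(), "sd_af": props[:, 2].std(ddof=1),
                    "n": len(ests),
                }
            )
    return pd.DataFrame(rows)


def replicate_concordance_experiment(
    panel_a: ParentalPanel,
    panel_b: ParentalPanel,
    truth: CohortTruth,
    seed: int | None = None,
    grid_step: float = 0.001,
    geno_a: GenotypeMatrix | None = None,
    geno_b: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Agreement of ancestry estimates from two disjoint marker panels.

    Every individual is estimated once with each panel (genotypes simulated
    independently per panel unless supplied) and the per-component
    differences (panel_a - panel_b) are summarized.  For balanced panels the
    mean difference should sit near zero with a symmetric spread.
    """
    if set(panel_a.snp_ids) & set(panel_b.snp_ids):
        raise ValidationError("replicate panels must not share SNP ids")
    rng = np.random.default_rng(seed)
    if geno_a is None:
        geno_a = simulate_cohort(panel_a, truth, seed=int(rng.integers(2**31)))
    if geno_b is None:
        geno_b = simulate_cohort(panel_b, truth, seed=int(rng.integers(2**31)))
    est_a = estimate_cohort(geno_a, grid_step=grid_step, on_degenerate="nan")
    est_b = estimate_cohort(geno_b, grid_step=grid_step, on_degenerate="nan")
    diff = np.array([ea.proportions - eb.proportions for ea, eb in zip(est_a, est_b)])
    rows = []
    for k, comp in enumerate(("eu", "ai", "af")):
        rows.append(
            {
                "component": comp,
                "mean_diff": float(diff[:, k].mean()),
                "median_diff": float(np.median(diff[:, k])),
                "sd_diff": float(diff[:, k].std(ddof=1)),
                "n": diff.shape[0],
            }
        )
    return pd.DataFrame(rows)
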