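"""Ancestry-informative-marker statistics and balanced panel construction.

A three-ancestry model has three pairwise information contrasts (EU-AI,
EU-AF, AI-AF).  The per-marker informativeness for a contrast is delta, the
absolute allele-frequency difference between the two populations.  Panels are
built from three marker sets, each maximized for one contrast (delta >= 0.5
in that contrast, delta < 0.3 in the other two), and audited for balance with
the informativeness-for-assignment statistic In and with Weir-Cockerham
F-statistics.  Balance matters because a maximum-likelihood ancestry model
fed markers informative for only some contrasts returns unstable, incorrect
estimates for the unrepresented component — with a large standard error as
the only internal warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SelectionError, ValidationError
from .panel_io import SET_LABELS, ParentalPanel

logger = logging.getLogger(__name__)

#: Default selection thresholds: maximized-contrast delta, off-contrast delta
#: ceiling, minimum bp separation within a set, replicate-discordance ceiling.
DELTA_MAX_DEFAULT = 0.5
DELTA_OFF_DEFAULT = 0.3
SPACING_BP_DEFAULT = 500_000
REPLICATE_MAX_DEFAULT = 0.032

#: Ambiguous allele pairs whose strand cannot be resolved between platforms.
AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

# Column pairs (population indices into (EU, AI, AF)) for each contrast.
_CONTRAST_POPS: dict[str, tuple[int, int]] = {
    "EU-AI": (0, 1),
    "EU-AF": (0, 2),
    "AI-AF": (1, 2),
}


def pairwise_deltas(panel: ParentalPanel) -> pd.DataFrame:
    """Absolute allele-frequency differences for the three contrasts.

    Returns a frame with columns ``snp_id``, ``delta_eu_ai``, ``delta_eu_af``,
    ``delta_ai_af``.
    """
    f = panel.freqs()
    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "delta_eu_ai": np.abs(f[:, 0] - f[:, 1]),
            "delta_eu_af": np.abs(f[:, 0] - f[:, 2]),
            "delta_ai_af": np.abs(f[:, 1] - f[:, 2]),
        }
    )


_DELTA_COL = {"EU-AI": "delta_eu_ai", "EU-AF": "delta_eu_af", "AI-AF": "delta_ai_af"}


def classify_contrasts(
    panel: ParentalPanel,
    delta_max: float = DELTA_MAX_DEFAULT,
    delta_off: float = DELTA_OFF_DEFAULT,
) -> pd.DataFrame:
    """Label each SNP with its maximized contrast, if any.

    A SNP is maximized for a contrast when that contrast's delta is at least
    ``delta_max`` while both other deltas are below ``delta_off``.  With
    delta_max >= 0.5 > delta_off at most one contrast can qualify, so the
    labels are mutually exclusive by construction.  SNPs qualifying for no
    contrast get label ``"none"``.
    """
    rec = pairwise_deltas(panel)
    labels = np.full(panel.G, "none", dtype=object)
    for label, col in _DELTA_COL.items():
        others = [c for c in _DELTA_COL.values() if c != col]
        hit = (
            (rec[col] >= delta_max)
            & (rec[others[0]] < delta_off)
            & (rec[others[1]] < delta_off)
        ).to_numpy()
        clash = hit & (labels != "none")
        if clash.any():  # impossible for delta_max > 2*delta_off; guard anyway
            raise ValidationError("a SNP matched two maximized contrasts")
        labels[hit] = label
    rec["maximized_contrast"] = labels
    return rec


def informativeness_in(
    freqs: np.ndarray,
    allele_mode: Literal["both-alleles", "allele1-only"] = "both-alleles",
) -> float:
    """Informativeness-for-assignment (In) of a marker set across K populations.

    ``freqs`` is an (n_snps, K) array of allele-1 frequencies.  Per SNP and
    allele the contribution is ``-pbar*ln(pbar) + sum_i (p_i/K)*ln(p_i)``
    with pbar the across-population mean and the convention 0*ln0 = 0; the
    statistic sums contributions over SNPs.  In both-alleles mode (the
    statistic's standard biallelic form, which is non-negative) the term is
    evaluated for allele 1 and allele 2 and added; allele1-only mode sums the
    allele-1 term alone.  Natural logarithm.  Additive over disjoint SNP sets.
    """
    p = np.atleast_2d(np.asarray(freqs, dtype=float))
    if p.size == 0:
        raise ValidationError("In is undefined for an empty SNP set")
    if p.shape[1] < 2:
        raise ValidationError("In requires at least K=2 populations")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("frequencies must lie in [0, 1]")

    def term(q: np.ndarray) -> float:
        qbar = q.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent_mean = np.where(qbar > 0, -qbar * np.log(qbar), 0.0)
            mean_ent = np.where(q > 0, q * np.log(q), 0.0).mean(axis=1)
        return float(np.sum(ent_mean + mean_ent))

    total = term(p)
    if allele_mode == "both-alleles":
        total += term(1.0 - p)
    elif allele_mode != "allele1-only":
        raise ValueError(f"unknown allele_mode {allele_mode!r}")
    return total


def weir_cockerham_fst(
    counts_pop1: Mapping[str, np.ndarray] | pd.DataFrame,
    counts_pop2: Mapping[str, np.ndarray] | pd.DataFrame,
) -> np.ndarray:
    """Per-SNP Weir-Cockerham theta for two population samples.

    Each argument provides, per SNP: ``n`` (genotyped individuals), ``het``
    (heterozygote count) and ``allele1`` (allele-1 count, 0..2n).  Returns
    theta-hat from the variance components a (among populations), b (among
    individuals within populations) and c (within individuals); sites
    monomorphic in both samples are NaN (theta undefined).
    """
    pops = []
    for counts in (counts_pop1, counts_pop2):
        n = np.asarray(counts["n"], dtype=float)
        het = np.asarray(counts["het"], dtype=float)
        a1 = np.asarray(counts["allele1"], dtype=float)
        if (n <= 0).any():
            raise ValidationError("sample sizes must be positive at every SNP")
        pops.append((n, a1 / (2.0 * n), het / n))
    (n1, p1, h1), (n2, p2, h2) = pops

    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        theta = a / (a + b + c)
    mono = (pbar == 0.0) | (pbar == 1.0)
    theta = np.where(mono, np.nan, theta)
    return theta


def fst_summary(theta: np.ndarray) -> dict[str, float]:
    """Mean/SD of per-SNP theta plus the count of undefined (monomorphic) sites."""
    ok = np.isfinite(theta)
    return {
        "mean": float(np.mean(theta[ok])) if ok.any() else float("nan"),
        "sd": float(np.std(theta[ok], ddof=1)) if ok.sum() > 1 else float("nan"),
        "n_defined": int(ok.sum()),
        "n_undefined": int((~ok).sum()),
    }


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {str(a1).upper(), str(a2).upper()} in AMBIGUOUS_PAIRS


@dataclass
class PanelBalanceReport:
    """Balance audit of a labeled AIM panel.

    Per maximized set: SNP count, In (over the two populations of its own
    contrast), mean/SD of the maximized delta.  Per contrast over all SNPs:
    In and mean delta.  The verdict is ``balanced`` when the three all-SNP
    In values agree within ``tolerance`` (relative max/min spread).
    """

    per_set: pd.DataFrame = field(repr=False)
    per_contrast_all: pd.DataFrame = field(repr=False)
    balanced: bool
    tolerance: float

    def to_dict(self) -> dict:
        return {
            "per_set": self.per_set.to_dict(orient="records"),
            "per_contrast_all_snps": self.per_contrast_all.to_dict(orient="records"),
            "balanced": bool(self.balanced),
            "tolerance": self.tolerance,
        }


def balance_report(
    panel: ParentalPanel,
    genotype_counts: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    tolerance: float = 0.10,
    in_scope: Literal["pair", "all"] = "pair",
    allele_mode: Literal["both-alleles", "allele1-only"] = "both-alleles",
) -> PanelBalanceReport:
    """Audit the information balance of a set-labeled panel.

    ``genotype_counts``, when given, maps population names ("EU", "AI",
    "AF") to per-SNP genotype count tables (see :func:`weir_cockerham_fst`)
    aligned to the panel, enabling mean-Fst columns.  ``in_scope`` selects
    whether per-set In uses the two populations of the maximized contrast
    (default) or all three.
    """
    labels = panel.set_labels
    if labels is None:
        raise ValidationError("balance_report needs a panel with set_label")
    deltas = pairwise_deltas(panel)
    f = panel.freqs()

    set_rows = []
    for label in SET_LABELS:
        mask = labels == label
        if not mask.any():
            set_rows.append({"set": label, "n_snps": 0, "in": float("nan"),
                             "mean_delta": float("nan"), "sd_delta": float("nan")})
            continue
        i, j = _CONTRAST_POPS[label]
        cols = [i, j] if in_scope == "pair" else [0, 1, 2]
        dvals = deltas.loc[mask, _DELTA_COL[label]]
        row = {
            "set": label,
            "n_snps": int(mask.sum()),
            "in": informativeness_in(f[np.ix_(mask, cols)], allele_mode),
            "mean_delta": float(dvals.mean()),
            "sd_delta": float(dvals.std(ddof=1)) if mask.sum() > 1 else float("nan"),
        }
        if genotype_counts is not None:
            pa, pb = label.split("-")
            theta = weir_cockerham_fst(
                _subset_counts(genotype_counts[pa], mask),
                _subset_counts(genotype_counts[pb], mask),
            )
            row["mean_fst"] = fst_summary(theta)["mean"]
        set_rows.append(row)

    all_rows = []
    for label in SET_LABELS:
        i, j = _CONTRAST_POPS[label]
        row = {
            "contrast": label,
            "in": informativeness_in(f[:, [i, j]], allele_mode),
            "mean_delta": float(deltas[_DELTA_COL[label]].mean()),
        }
        if genotype_counts is not None:
            pa, pb = label.split("-")
            theta = weir_cockerham_fst(genotype_counts[pa], genotype_counts[pb])
            row["mean_fst"] = fst_summary(theta)["mean"]
        all_rows.append(row)

    ins = np.array([r["in"] for r in all_rows])
    balanced = bool(np.nanmax(ins) / np.nanmin(ins) <= 1.0 + tolerance)
    return PanelBalanceReport(
        per_set=pd.DataFrame(set_rows),
        per_contrast_all=pd.DataFrame(all_rows),
        balanced=balanced,
        tolerance=tolerance,
    )


def _subset_counts(counts, mask):
    return {k: np.asarray(counts[k])[mask] for k in ("n", "het", "allele1")}


def select_aims(
    candidates: ParentalPanel,
    delta_max: float = DELTA_MAX_DEFAULT,
    delta_off: float = DELTA_OFF_DEFAULT,
    spacing_bp: int = SPACING_BP_DEFAULT,
    replicate_max: float = REPLICATE_MAX_DEFAULT,
    set_sizes: Sequence[int] | Mapping[str, int] | None = None,
    genotype_counts=None,
) -> tuple[ParentalPanel, PanelBalanceReport]:
    """Build a balanced AIM panel from a candidate frequency table.

    Pipeline: (1) drop strand-ambiguous A/T and C/G SNPs; (2) drop SNPs with
    replicate discordance above ``replicate_max`` when that column exists;
    (3) label maximized contrasts; (4) within each contrast class, greedily
    accept SNPs in descending maximized-delta order (ties by position)
    subject to at least ``spacing_bp`` separation from already-accepted SNPs
    of the same set on the same chromosome; (5) if ``set_sizes`` is given
    ((EU-AI, EU-AF, AI-AF) order, or a mapping), truncate each set to its
    target, dropping the lowest-delta members.  Returns the labeled panel and
    its balance report.
    """
    df = candidates.df.copy()
    amb = df.apply(lambda r: _is_ambiguous(r["allele1"], r["allele2"]), axis=1)
    n_amb = int(amb.sum())
    df = df[~amb.to_numpy()].reset_index(drop=True)
    if "replicate_discordance" in df.columns:
        rep = pd.to_numeric(df["replicate_discordance"], errors="coerce")
        bad = (rep > replicate_max).to_numpy()
        df = df[~bad].reset_index(drop=True)
        logger.info("dropped %d ambiguous and %d high-discordance candidates",
                    n_amb, int(bad.sum()))
    if df.empty:
        raise SelectionError("no candidates survive the ambiguity/discordance filters")
    filtered = ParentalPanel(df)
    rec = classify_contrasts(filtered, delta_max, delta_off)

    if isinstance(set_sizes, Mapping):
        targets = dict(set_sizes)
    elif set_sizes is not None:
        targets = dict(zip(SET_LABELS, set_sizes))
    else:
        targets = {}

    chosen_idx: list[int] = []
    chosen_label: list[str] = []
    for label in SET_LABELS:
        col = _DELTA_COL[label]
        cls = rec.index[(rec["maximized_contrast"] == label)].to_numpy()
        if cls.size == 0:
            raise SelectionError(
                f"no candidate is maximized for contrast {label}; "
                "a balanced panel cannot be built"
            )
        sub = filtered.df.iloc[cls]
        order = cls[np.lexsort((sub["pos"].to_numpy(), -rec.loc[cls, col].to_numpy()))]
        taken: dict[str, list[int]] = {}
        kept = []
        for idx in order:
            chrom = filtered.df["chrom"].iloc[idx]
            pos = int(filtered.df["pos"].iloc[idx])
            near = taken.get(chrom, [])
            if all(abs(pos - q) >= spacing_bp for q in near):
                kept.append(idx)
                taken.setdefault(chrom, []).append(pos)
        if label in targets and len(kept) > targets[label]:
            # kept is in descending delta order; truncation drops the weakest
            kept = kept[: targets[label]]
        chosen_idx.extend(kept)
        chosen_label.extend([label] * len(kept))

    out = filtered.df.iloc[chosen_idx].copy()
    out["set_label"] = chosen_label
    selected = ParentalPanel(out.reset_index(drop=True))
    report = balance_report(selected, genotype_counts=genotype_counts)
    return selected, report
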