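"""Reading and writing parental frequency panels, genotype matrices and
estimate tables.

The parental panel is the single source of allele orientation: every genotype
input (TSV dosages or VCF) is mapped onto the panel's allele 1.  Ambiguous
strand-flippable pairs (A/T, C/G) are expected to be excluded upstream by the
AIM selection filter, so no strand flipping is ever attempted here; allele
pairs that do not match are rejected or skipped.

Conventions: positions are 1-based; the TSV missing-genotype token is "NA"
(configurable); frequencies are allele-1 frequencies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    NoDataError,
    OrientationError,
    PanelFormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Canonical panel columns.  ``replicate_discordance`` and ``set_label`` are
#: optional.  ``p_eu``/``p_ai``/``p_af`` are allele-1 frequencies in the
#: European, American Indian and African reference populations.
PANEL_COLUMNS = ("snp_id", "chrom", "pos", "allele1", "allele2", "p_eu", "p_ai", "p_af")
OPTIONAL_COLUMNS = ("replicate_discordance", "set_label")

FREQ_COLUMNS = ("p_eu", "p_ai", "p_af")

#: Contrast-set labels, in the conventional order.
SET_LABELS = ("EU-AI", "EU-AF", "AI-AF")


@dataclass
class ParentalPanel:
    """An ordered table of reference-population allele frequencies.

    Wraps a :class:`pandas.DataFrame` with the canonical columns, sorted by
    (chrom, pos).  These frequencies are the fixed quantities of the
    fixed-parental-allele likelihood; ``G`` is the number of SNPs.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = _validate_panel_frame(self.df)

    @property
    def G(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    def freqs(self) -> np.ndarray:
        """Allele-1 frequencies as a (G, 3) array in (EU, AI, AF) order."""
        return self.df[list(FREQ_COLUMNS)].to_numpy(dtype=float)

    @property
    def p_eu(self) -> np.ndarray:
        return self.df["p_eu"].to_numpy(dtype=float)

    @property
    def p_ai(self) -> np.ndarray:
        return self.df["p_ai"].to_numpy(dtype=float)

    @property
    def p_af(self) -> np.ndarray:
        return self.df["p_af"].to_numpy(dtype=float)

    @property
    def set_labels(self) -> np.ndarray | None:
        if "set_label" in self.df.columns:
            return self.df["set_label"].to_numpy()
        return None

    def subset(self, mask_or_idx) -> "ParentalPanel":
        """A new panel restricted to the given boolean mask or index array."""
        sub = self.df.iloc[np.arange(self.G)[mask_or_idx]] if np.asarray(
            mask_or_idx
        ).dtype == bool else self.df.iloc[mask_or_idx]
        return ParentalPanel(sub.reset_index(drop=True))

    def __len__(self) -> int:
        return self.G


def _validate_panel_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel is missing required column(s): {missing}")
    df = df.copy()
    for col in FREQ_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > 1)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"column {col!r} has a frequency outside [0,1] at row {row} "
                f"(snp {df['snp_id'].iloc[row]!r}, value {df[col].iloc[row]!r})"
            )
        df[col] = vals.astype(float)
    same = df["allele1"].astype(str) == df["allele2"].astype(str)
    if same.any():
        row = int(np.flatnonzero(same.to_numpy())[0])
        raise ValidationError(f"allele1 == allele2 at row {row} (snp {df['snp_id'].iloc[row]!r})")
    df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"duplicate (chrom, pos) at row {row}: "
            f"({df['chrom'].iloc[row]}, {df['pos'].iloc[row]})"
        )
    # Sort numerically by chromosome where labels are numeric strings.
    key = pd.to_numeric(df["chrom"], errors="coerce")
    if key.isna().any():
        key = df["chrom"].astype(str)
    df = (
        df.assign(_ck=key)
        .sort_values(["_ck", "pos"], kind="mergesort")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )
    return df


def read_panel(path: str | Path, dialect: Mapping[str, str] | None = None) -> ParentalPanel:
    """Read a parental frequency panel from a TSV file.

    Parameters
    ----------
    path
        Tab-separated table with the canonical columns (see module docstring).
    dialect
        Optional mapping from the file's column names to canonical names,
        e.g. ``{"rsid": "snp_id", "freq_ceu": "p_eu"}``, so externally
        produced AIM tables can be ingested without editing.
    """
    path = Path(path)
    if not path.exists():
        raise PanelFormatError(f"panel file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if dialect:
        df = df.rename(columns=dict(dialect))
    return ParentalPanel(df)


def write_panel(panel: ParentalPanel, path: str | Path) -> None:
    """Write a panel back to TSV with full float precision."""
    panel.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def average_reference_freqs(
    freqs_a: pd.DataFrame, freqs_b: pd.DataFrame
) -> pd.DataFrame:
    """Merge two reference frequency tables into one, averaging shared SNPs.

    Emulates pooling two reference samples for one ancestral population
    (e.g. two African reference panels): when a SNP is present in both, the
    unweighted mean frequency is used; when present in only one, that value
    is used singly.  Each table must have columns ``snp_id``, ``allele1``,
    ``allele2``, ``freq``.

    Returns a table with columns ``snp_id``, ``allele1``, ``allele2``,
    ``freq``, ``source`` where source is "both", "a" or "b".
    """
    for name, t in (("freqs_a", freqs_a), ("freqs_b", freqs_b)):
        need = {"snp_id", "allele1", "allele2", "freq"}
        if not need.issubset(t.columns):
            raise PanelFormatError(f"{name} is missing columns {need - set(t.columns)}")
    merged = freqs_a.merge(
        freqs_b, on="snp_id", how="outer", suffixes=("_a", "_b"), indicator=True
    )
    both = merged["_merge"] == "both"
    if both.any():
        conflict = both & (
            (merged["allele1_a"] != merged["allele1_b"])
            | (merged["allele2_a"] != merged["allele2_b"])
        )
        if conflict.any():
            snp = merged.loc[conflict, "snp_id"].iloc[0]
            raise OrientationError(
                f"allele orientation conflict for shared SNP {snp!r}: "
                "the two tables disagree on the allele pair"
            )
    freq = np.where(
        both,
        (merged["freq_a"] + merged["freq_b"]) / 2.0,
        merged["freq_a"].fillna(merged["freq_b"]),
    )
    out = pd.DataFrame(
        {
            "snp_id": merged["snp_id"],
            "allele1": merged["allele1_a"].fillna(merged["allele1_b"]),
            "allele2": merged["allele2_a"].fillna(merged["allele2_b"]),
            "freq": freq,
            "source": merged["_merge"].map({"both": "both", "left_only": "a", "right_only": "b"}),
        }
    )
    return out


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-1 dosages aligned to a parental panel.

    ``dosages`` is a float array with entries in {0, 1, 2} and NaN for
    missing; columns follow the panel's SNP order exactly.
    """

    sample_ids: list[str]
    dosages: np.ndarray
    panel: ParentalPanel = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D array")
        if self.dosages.shape != (len(self.sample_ids), self.panel.G):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.panel.G} panel SNPs"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.argwhere(
                ~np.isnan(self.dosages) & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
            )[0]
            raise ValidationError(
                f"dosage {self.dosages[tuple(bad)]} outside {{0,1,2}} for sample "
                f"{self.sample_ids[bad[0]]!r}, SNP {self.panel.snp_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def read_genotypes_tsv(
    path: str | Path, panel: ParentalPanel, missing_token: str = "NA"
) -> GenotypeMatrix:
    """Read an allele-1 dosage matrix (samples x SNPs) and align it to a panel.

    The header row is ``sample_id`` followed by SNP ids; columns are reordered
    to panel order and panel SNPs absent from the file become missing for
    every sample (logged).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise PanelFormatError("genotype TSV must start with a 'sample_id' column")
    sample_ids = df["sample_id"].tolist()
    body = df.drop(columns="sample_id")
    body = body.replace(missing_token, np.nan)
    mat = body.to_numpy(dtype=float)
    ok = np.isnan(mat) | np.isin(mat, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValidationError(
            f"dosage {mat[i, j]!r} outside {{0,1,2,{missing_token}}} for sample "
            f"{sample_ids[i]!r}, SNP {body.columns[j]!r}"
        )
    col_index = {s: k for k, s in enumerate(body.columns)}
    out = np.full((len(sample_ids), panel.G), np.nan)
    n_absent = 0
    for g, snp in enumerate(panel.snp_ids):
        k = col_index.get(snp)
        if k is None:
            n_absent += 1
        else:
            out[:, g] = mat[:, k]
    if n_absent:
        logger.info("%d panel SNPs absent from %s; set missing for all samples", n_absent, path)
    return GenotypeMatrix(sample_ids, out, panel)


def write_genotypes_tsv(
    geno: GenotypeMatrix, path: str | Path, missing_token: str = "NA"
) -> None:
    """Write a dosage matrix as TSV (inverse of :func:`read_genotypes_tsv`)."""
    df = pd.DataFrame(geno.dosages, columns=geno.panel.snp_ids)
    df = df.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    df.insert(0, "sample_id", geno.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def dosages_from_vcf(path: str | Path, panel: ParentalPanel) -> GenotypeMatrix:
    """Extract allele-1 dosages for panel SNPs from a VCF.

    Sites are matched by (chrom, pos); the VCF's {REF, ALT} pair must equal
    the panel's allele pair, and the dosage is counted with respect to the
    panel's allele 1 regardless of which of REF/ALT it is.  Mismatching
    allele pairs are skipped and logged; half-calls and missing genotypes
    become missing.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    site_index = {
        (str(row.chrom), int(row.pos)): g
        for g, row in enumerate(panel.df.itertuples())
    }
    out = np.full((len(sample_ids), panel.G), np.nan)
    n_matched = 0
    n_skipped = 0
    for var in vcf:
        g = site_index.get((str(var.CHROM), int(var.POS)))
        if g is None:
            continue
        row = panel.df.iloc[g]
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        pair = {var.REF, var.ALT[0]}
        if pair != {row["allele1"], row["allele2"]}:
            n_skipped += 1
            logger.info(
                "allele pair mismatch at %s:%s (VCF %s, panel %s/%s); skipped",
                var.CHROM, var.POS, pair, row["allele1"], row["allele2"],
            )
            continue
        # genotypes: rows [a, b, phased]; -1 encodes a missing allele call
        gts = np.array(var.genotypes, dtype=int)[:, :2]
        alt_dose = (gts == 1).sum(axis=1).astype(float)
        alt_dose[(gts < 0).any(axis=1)] = np.nan  # half-calls and ./. -> missing
        if row["allele1"] == var.ALT[0]:
            out[:, g] = alt_dose
        else:
            out[:, g] = 2.0 - alt_dose
        n_matched += 1
    if n_matched == 0:
        raise NoDataError(f"no VCF site in {path} matched the panel")
    if n_skipped:
        logger.info("%d VCF sites skipped for allele-pair mismatch", n_skipped)
    return GenotypeMatrix(sample_ids, out, panel)


ESTIMATE_COLUMNS = (
    "sample_id",
    "n_snps_used",
    "m_eu",
    "m_ai",
    "m_af",
    "se_eu",
    "se_ai",
    "se_af",
    "cov_eu_ai",
)


def write_estimates(estimates: Sequence, path: str | Path) -> None:
    """Write ancestry estimates as a TSV (one row per individual).

    ``estimates`` is a sequence of :class:`aimix.mle.AdmixtureEstimate`.
    Values round-trip at better than 1e-6.
    """
    rows = [
        {
            "sample_id": e.sample_id,
            "n_snps_used": e.n_snps_used,
            "m_eu": e.m1,
            "m_ai": e.m2,
            "m_af": e.m3,
            "se_eu": e.se_m1,
            "se_ai": e.se_m2,
            "se_af": e.se_m3,
            "cov_eu_ai": e.cov_m1m2,
        }
        for e in estimates
    ]
    df = pd.DataFrame(rows, columns=list(ESTIMATE_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_estimates(path: str | Path) -> pd.DataFrame:
    """Read an estimates TSV written by :func:`write_estimates`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"estimates table missing column(s): {missing}")
    return df
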