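"""Synthetic parental panels and admixed cohorts with known truth.

The panel generator emulates a balanced three-contrast AIM panel: three sets
of markers, each maximized for one pairwise contrast (maximized delta drawn
from a truncated normal around 0.53, both off-contrast deltas below 0.3),
placed on 22 pseudo-chromosomes with generous spacing so linkage
disequilibrium never needs to be modeled.  The cohort generator draws
genotypes from the same HWE model the estimator assumes — dosage ~
Binomial(2, P_h) with P_h the hybrid frequency at the individual's true
ancestry — so estimator properties (consistency, SE calibration, balance
failure) are testable without any external data.  What it deliberately does
not emulate: LD between markers, genotyping error, HWE departures, or drift
between the reference samples and the true ancestral populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .panel_io import SET_LABELS, GenotypeMatrix, ParentalPanel

#: Group mean ancestry (EU, AI, AF) of the four admixed-cohort archetypes the
#: generator reproduces: mostly-European, mostly-American-Indian, three-way
#: admixed Mexican American, and African American groups.
FIND_GROUP_MEANS: dict[str, tuple[float, float, float]] = {
    "European American": (0.961, 0.014, 0.025),
    "American Indian": (0.045, 0.945, 0.010),
    "Mexican American": (0.476, 0.447, 0.077),
    "African American": (0.149, 0.021, 0.830),
}

#: Default Dirichlet concentration: chosen so the per-group component SDs are
#: of order 0.05-0.13, the spread typical of self-identified admixed cohorts.
DEFAULT_CONCENTRATION = 13.0

_N_CHROMS = 22
_POS_STEP = 600_000  # > the 500 kb spacing rule, applied to all neighbors

# Unambiguous allele pairs (A/T and C/G are excluded from AIM panels).
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))

_CONTRAST_COLS: dict[str, tuple[int, int, int]] = {
    # (maximized pop a, maximized pop b, off population), indices into (EU, AI, AF)
    "EU-AI": (0, 1, 2),
    "EU-AF": (0, 2, 1),
    "AI-AF": (1, 2, 0),
}


@dataclass
class PanelSimConfig:
    """Parameters of the synthetic AIM panel.

    set_sizes: SNPs per maximized contrast in (EU-AI, EU-AF, AI-AF) order.
    delta_mean/delta_sd: normal law of the maximized delta, truncated to
    [0.5, 1].  delta_off_max: ceiling on both off-contrast deltas.
    freq_floor: all parental frequencies kept in [floor, 1 - floor].
    """

    set_sizes: tuple[int, int, int] = (450, 450, 400)
    delta_mean: float = 0.53
    delta_sd: float = 0.022
    delta_off_max: float = 0.3
    freq_floor: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.delta_mean < 0.5:
            raise ConfigError("delta_mean must be >= 0.5 (the maximized-contrast rule)")
        if not 0 < self.delta_off_max < 0.5:
            raise ConfigError("delta_off_max must lie in (0, 0.5)")
        if any(s <= 0 for s in self.set_sizes):
            raise ConfigError("set sizes must be positive")
        if not 0 < self.freq_floor < 0.5:
            raise ConfigError("freq_floor must lie in (0, 0.5)")


def simulate_panel(
    config: PanelSimConfig | None = None,
    seed: int | None = None,
    id_prefix: str = "snp",
) -> ParentalPanel:
    """Generate a balanced synthetic AIM panel.

    For each SNP of a set, the maximized contrast's delta is drawn from
    Normal(delta_mean, delta_sd) truncated to [0.5, 1]; the lower of the two
    contrast frequencies is uniform given feasibility; the off-population
    frequency is uniform on the window where both off-contrast deltas stay
    below ``delta_off_max``.  Draws with an empty window (delta too large)
    are rejected and retried.  SNPs are laid out on 22 pseudo-chromosomes at
    600 kb spacing with the three sets interleaved in genome order.
    Bit-reproducible for a fixed seed.
    """
    config = config or PanelSimConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    n_total = sum(config.set_sizes)
    labels = np.repeat(SET_LABELS, config.set_sizes)
    rng.shuffle(labels)  # interleave the sets along the genome

    lo, hi = config.freq_floor, 1.0 - config.freq_floor
    a, b = (0.5 - config.delta_mean) / config.delta_sd, (1.0 - config.delta_mean) / config.delta_sd
    eps = 1e-9

    freqs = np.empty((n_total, 3))
    max_attempts = 10_000
    for g, label in enumerate(labels):
        ia, ib, iz = _CONTRAST_COLS[label]
        for attempt in range(max_attempts):
            delta = float(
                stats.truncnorm.rvs(a, b, loc=config.delta_mean, scale=config.delta_sd,
                                    random_state=rng)
            )
            if delta >= 2 * config.delta_off_max or delta > hi - lo:
                continue  # no off-population window / no room for the pair
            p_low = rng.uniform(lo, hi - delta)
            p_high = p_low + delta
            z_lo = max(lo, p_high - config.delta_off_max + eps)
            z_hi = min(hi, p_low + config.delta_off_max - eps)
            if z_lo >= z_hi:
                continue
            p_off = rng.uniform(z_lo, z_hi)
            pa, pb = (p_low, p_high) if rng.random() < 0.5 else (p_high, p_low)
            row = np.empty(3)
            row[ia], row[ib], row[iz] = pa, pb, p_off
            freqs[g] = row
            break
        else:
            raise ConfigError(
                f"panel simulation infeasible: {max_attempts} rejected draws for a "
                f"{label} SNP under {config!r}"
            )

    per_chrom = int(np.ceil(n_total / _N_CHROMS))
    chroms = [str(g // per_chrom + 1) for g in range(n_total)]
    pos = [(g % per_chrom + 1) * _POS_STEP for g in range(n_total)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n_total)
    df = pd.DataFrame(
        {
            "snp_id": [f"{id_prefix}{g + 1:05d}" for g in range(n_total)],
            "chrom": chroms,
            "pos": pos,
            "allele1": [_ALLELE_PAIRS[k][0] for k in pair_idx],
            "allele2": [_ALLELE_PAIRS[k][1] for k in pair_idx],
            "p_eu": freqs[:, 0],
            "p_ai": freqs[:, 1],
            "p_af": freqs[:, 2],
            "set_label": labels,
        }
    )
    return ParentalPanel(df)


@dataclass
class CohortTruth:
    """True per-individual ancestry proportions (the generative parameters)."""

    proportions: np.ndarray  # (n, 3), rows on the simplex
    group: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2 or self.proportions.shape[1] != 3:
            raise ValidationError("truth proportions must be an (n, 3) array")
        if (self.proportions < -1e-12).any() or np.abs(
            self.proportions.sum(axis=1) - 1.0
        ).max() > 1e-9:
            raise ValidationError("each truth row must be a point on the ancestry simplex")
        n = len(self.proportions)
        if not self.group:
            self.group = [""] * n
        if not self.sample_ids:
            self.sample_ids = [f"ind{i + 1:05d}" for i in range(n)]

    @property
    def n(self) -> int:
        return len(self.proportions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": self.group,
                "mu_eu": self.proportions[:, 0],
                "mu_ai": self.proportions[:, 1],
                "mu_af": self.proportions[:, 2],
            }
        )


def find_like_truth(
    n_per_group: int | Mapping[str, int] = 100,
    concentration: float = DEFAULT_CONCENTRATION,
    seed: int | None = None,
    group_means: Mapping[str, Sequence[float]] | None = None,
) -> CohortTruth:
    """Draw individual truths for a four-group admixed cohort.

    Each group's individuals are Dirichlet draws centered on the group's mean
    ancestry with concentration ``concentration`` (alpha = concentration *
    mean); ``concentration=numpy.inf`` degenerates to every individual
    exactly at the group mean.
    """
    if not np.isinf(concentration) and concentration <= 0:
        raise ValidationError("concentration must be positive")
    means = {k: np.asarray(v, float) for k, v in (group_means or FIND_GROUP_MEANS).items()}
    for k, v in means.items():
        if v.shape != (3,) or abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
            raise ValidationError(f"group mean for {k!r} is not on the simplex")
    if isinstance(n_per_group, int):
        n_per_group = {k: n_per_group for k in means}
    rng = np.random.default_rng(seed)
    rows, groups = [], []
    for name, mean in means.items():
        n = int(n_per_group[name])
        if n <= 0:
            raise ValidationError("n_per_group must be positive")
        if np.isinf(concentration):
            draws = np.tile(mean, (n, 1))
        else:
            draws = rng.dirichlet(concentration * mean, size=n)
        rows.append(draws)
        groups.extend([name] * n)
    return CohortTruth(np.vstack(rows), group=groups)


def simulate_cohort(
    panel: ParentalPanel,
    truth: CohortTruth,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Draw genotypes for a cohort under the HWE admixture model.

    Each dosage is Binomial(2, P_h) with P_h the hybrid allele-1 frequency at
    the individual's true (mu1, mu2); entries are independently masked
    missing at ``missing_rate``.  Bit-reproducible for a fixed seed.
    """
    if not 0.0 <= missing_rate <= 0.5:
        raise ValidationError("missing_rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    mu = truth.proportions
    d1 = panel.p_eu - panel.p_af
    d2 = panel.p_ai - panel.p_af
    P = panel.p_af[None, :] + np.outer(mu[:, 0], d1) + np.outer(mu[:, 1], d2)
    P = np.clip(P, 0.0, 1.0)  # guard float round-off at the simplex vertices
    dos = rng.binomial(2, P).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    return GenotypeMatrix(list(truth.sample_ids), dos, panel)
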