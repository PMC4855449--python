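"""Fixed-parental-allele maximum-likelihood estimation of three-way ancestry.

The model: an admixed individual derives proportions (m1, m2, m3) of their
genome from three ancestral populations (EU, AI, AF), m1 + m2 + m3 = 1.
Treating the reference allele frequencies as known constants, the expected
allele-1 frequency at SNP g in that individual is the convex combination

    P_h(g) = p_af(g) + m1 * d1(g) + m2 * d2(g),

where d1 = p_eu - p_af and d2 = p_ai - p_af.  Under Hardy-Weinberg
equilibrium the genotype log-likelihoods are ln(P_h^2), ln(2 P_h (1 - P_h))
and ln((1 - P_h)^2) for allele-1 dosages 2, 1, 0, and the total
log-likelihood sums over the non-missing SNPs.  (m1, m2) is found by
exhaustive evaluation on a lattice over the simplex m1 + m2 <= 1 (default
step 0.001), and m3 = 1 - m1 - m2.

Standard errors come from inverting the 2x2 information matrix at the
maximum.  The default uses expected (Fisher) information under the HWE
binomial,

    I_m1 = sum_g 2 d1^2 / (P (1-P)),   I_m1m2 = sum_g 2 d1 d2 / (P (1-P)),

with V(m3) = V(m1) + V(m2) + 2 Cov(m1, m2); observed information is
available via ``info="observed"`` for sensitivity analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateInformationError, NoDataError, ValidationError
from .panel_io import GenotypeMatrix, ParentalPanel

logger = logging.getLogger(__name__)

#: Default clamp for hybrid frequencies, keeping log-likelihoods finite when
#: a reference frequency is 0 or 1.
DEFAULT_CLAMP = 1e-3

#: Default lattice resolution over the ancestry simplex.
DEFAULT_GRID_STEP = 0.001

#: Coarse stage resolution and refinement half-width of the two-stage search.
COARSE_STEP = 0.01
REFINE_HALFWIDTH = 0.02

LN2 = float(np.log(2.0))


@dataclass
class DeltaSet:
    """Signed parental allele-frequency differences per SNP.

    d1/d2 are allele-1 differences (EU-AF, AI-AF); d3/d4 are the allele-2
    differences and for biallelic SNPs equal -d1 and -d2.
    """

    d1: np.ndarray
    d2: np.ndarray

    @property
    def d3(self) -> np.ndarray:
        return -self.d1

    @property
    def d4(self) -> np.ndarray:
        return -self.d2


@dataclass
class InformationMatrix:
    """Summed 2x2 information for (m1, m2)."""

    i_m1: float
    i_m2: float
    i_m1m2: float

    def as_array(self) -> np.ndarray:
        return np.array([[self.i_m1, self.i_m1m2], [self.i_m1m2, self.i_m2]])


@dataclass
class AdmixtureEstimate:
    """Point estimates, variances and standard errors for one individual."""

    m1: float
    m2: float
    m3: float
    v_m1: float
    v_m2: float
    cov_m1m2: float
    v_m3: float
    se_m1: float
    se_m2: float
    se_m3: float
    n_snps_used: int
    loglik: float
    sample_id: str = ""

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.m1, self.m2, self.m3])

    @property
    def standard_errors(self) -> np.ndarray:
        return np.array([self.se_m1, self.se_m2, self.se_m3])


def compute_deltas(panel: ParentalPanel) -> DeltaSet:
    """Per-SNP allele-frequency differences of the two estimated components."""
    return DeltaSet(d1=panel.p_eu - panel.p_af, d2=panel.p_ai - panel.p_af)


def _check_simplex(m1: float, m2: float) -> None:
    if m1 < -1e-12 or m2 < -1e-12 or m1 + m2 > 1 + 1e-12:
        raise ValidationError(f"(m1, m2) = ({m1}, {m2}) is outside the ancestry simplex")


def hybrid_freq(
    m1: float,
    m2: float,
    p_eu: np.ndarray | float,
    p_ai: np.ndarray | float,
    p_af: np.ndarray | float,
    clamp: float = DEFAULT_CLAMP,
) -> np.ndarray | float:
    """Expected allele-1 frequency in an admixed individual.

    Equals ``m1 * p_eu + m2 * p_ai + (1 - m1 - m2) * p_af``; clamped into
    ``[clamp, 1 - clamp]`` so downstream logarithms stay finite.
    """
    _check_simplex(m1, m2)
    p = np.asarray(p_af, dtype=float) + m1 * (np.asarray(p_eu) - p_af) + m2 * (
        np.asarray(p_ai) - p_af
    )
    return np.clip(p, clamp, 1.0 - clamp)


def genotype_loglik(dosage: int, p_h: float | np.ndarray) -> float | np.ndarray:
    """HWE log-likelihood of one genotype given hybrid allele-1 frequency."""
    p_h = np.asarray(p_h, dtype=float)
    if dosage == 2:
        out = 2.0 * np.log(p_h)
    elif dosage == 1:
        out = LN2 + np.log(p_h) + np.log1p(-p_h)
    elif dosage == 0:
        out = 2.0 * np.log1p(-p_h)
    else:
        raise ValidationError(f"dosage must be 0, 1 or 2, got {dosage!r}")
    return out if out.ndim else float(out)


def total_loglik(
    dosages: np.ndarray,
    panel: ParentalPanel,
    m1: float,
    m2: float,
    clamp: float = DEFAULT_CLAMP,
) -> float:
    """Log-likelihood of one individual's dosage vector, summed over
    non-missing SNPs."""
    d = np.asarray(dosages, dtype=float)
    if d.shape != (panel.G,):
        raise ValidationError(f"dosage vector length {d.shape} != panel G = {panel.G}")
    obs = ~np.isnan(d)
    if not obs.any():
        raise NoDataError("all genotypes are missing for this individual")
    p = hybrid_freq(m1, m2, panel.p_eu[obs], panel.p_ai[obs], panel.p_af[obs], clamp)
    dd = d[obs]
    return float(
        np.sum(dd * np.log(p) + (2.0 - dd) * np.log1p(-p)) + LN2 * np.sum(dd == 1.0)
    )


def simplex_grid(step: float) -> tuple[np.ndarray, np.ndarray]:
    """Lattice over {(m1, m2): m1, m2 >= 0, m1 + m2 <= 1}.

    Points are ordered by ascending m1, then ascending m2, so that the first
    occurrence of a maximal likelihood is the tie-break winner (smallest m1,
    then smallest m2).
    """
    k = int(round(1.0 / step))
    i = np.repeat(np.arange(k + 1), np.arange(k + 1, 0, -1))
    j = np.concatenate([np.arange(k + 1 - ii) for ii in range(k + 1)])
    return i * step, j * step


def _box_grid(
    center1: float, center2: float, halfwidth: float, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Simplex-clipped lattice of the given step in a box around a point,
    in the same lexicographic order as :func:`simplex_grid`."""
    k = int(round(1.0 / step))
    lo1 = max(0, int(round((center1 - halfwidth) / step)))
    hi1 = min(k, int(round((center1 + halfwidth) / step)))
    lo2 = max(0, int(round((center2 - halfwidth) / step)))
    hi2 = min(k, int(round((center2 + halfwidth) / step)))
    i, j = np.meshgrid(np.arange(lo1, hi1 + 1), np.arange(lo2, hi2 + 1), indexing="ij")
    i, j = i.ravel(), j.ravel()
    keep = i + j <= k
    return i[keep] * step, j[keep] * step


def _grid_loglik(
    m1s: np.ndarray,
    m2s: np.ndarray,
    panel: ParentalPanel,
    dosages: np.ndarray,
    clamp: float,
    chunk: int = 50_000,
) -> np.ndarray:
    """Log-likelihood (up to the per-individual het constant) of each grid
    point for each individual; returns an (n_points, n_individuals) array.

    Missing dosages contribute nothing: both d and 2-d are zeroed there.
    """
    D = np.atleast_2d(np.asarray(dosages, dtype=float))
    obs = ~np.isnan(D)
    Dz = np.where(obs, D, 0.0)
    Ez = np.where(obs, 2.0 - D, 0.0)
    p_eu, p_ai, p_af = panel.p_eu, panel.p_ai, panel.p_af
    out = np.empty((len(m1s), D.shape[0]))
    for start in range(0, len(m1s), chunk):
        sl = slice(start, min(start + chunk, len(m1s)))
        P = p_af[None, :] + np.outer(m1s[sl], p_eu - p_af) + np.outer(m2s[sl], p_ai - p_af)
        np.clip(P, clamp, 1.0 - clamp, out=P)
        lnP = np.log(P)
        ln1mP = np.log1p(-P)
        out[sl] = lnP @ Dz.T + ln1mP @ Ez.T
    return out


def information_matrix(
    dosages: np.ndarray,
    panel: ParentalPanel,
    m1: float,
    m2: float,
    clamp: float = DEFAULT_CLAMP,
    kind: Literal["expected", "observed"] = "expected",
) -> InformationMatrix:
    """2x2 information for (m1, m2), summed over non-missing SNPs.

    ``expected`` (default) is the Fisher information of the HWE binomial at
    the hybrid frequency P: per SNP, 2 d1^2 / (P(1-P)) etc.  ``observed`` is
    the negated Hessian of the realized log-likelihood.
    """
    d = np.asarray(dosages, dtype=float)
    obs = ~np.isnan(d)
    if not obs.any():
        raise NoDataError("all genotypes are missing for this individual")
    deltas = compute_deltas(panel)
    d1, d2 = deltas.d1[obs], deltas.d2[obs]
    P = hybrid_freq(m1, m2, panel.p_eu[obs], panel.p_ai[obs], panel.p_af[obs], clamp)
    if kind == "expected":
        w = 2.0 / (P * (1.0 - P))
    elif kind == "observed":
        dd = d[obs]
        w = dd / P**2 + (2.0 - dd) / (1.0 - P) ** 2
    else:
        raise ValueError(f"unknown information kind {kind!r}")
    return InformationMatrix(
        i_m1=float(np.sum(w * d1 * d1)),
        i_m2=float(np.sum(w * d2 * d2)),
        i_m1m2=float(np.sum(w * d1 * d2)),
    )


def invert_information(
    info: InformationMatrix, det_tol: float = 1e-10
) -> dict[str, float]:
    """Variances, covariance and standard errors from the information matrix.

    Raises :class:`DegenerateInformationError` when the matrix is singular or
    near-singular relative to its scale — the explicit form of the method's
    internal warning that a panel carries too little information for a
    contrast.
    """
    det = info.i_m1 * info.i_m2 - info.i_m1m2**2
    scale = max(info.i_m1 * info.i_m2, info.i_m1m2**2, 1.0)
    if not np.isfinite(det) or det <= det_tol * scale:
        raise DegenerateInformationError(
            f"information matrix is singular or near-singular (det = {det:.3g}); "
            "ancestry variances are undefined — the panel is uninformative for a contrast"
        )
    v1 = info.i_m2 / det
    v2 = info.i_m1 / det
    cov = -info.i_m1m2 / det
    v3 = v1 + v2 + 2.0 * cov
    # v3 = (i1 + i2 - 2*i12)/det >= 0 by Cauchy-Schwarz when det > 0, but
    # guard against float cancellation at extreme correlation.
    v3 = max(v3, 0.0)
    return {
        "v_m1": v1,
        "v_m2": v2,
        "cov_m1m2": cov,
        "v_m3": v3,
        "se_m1": float(np.sqrt(v1)),
        "se_m2": float(np.sqrt(v2)),
        "se_m3": float(np.sqrt(v3)),
    }


def _finish_estimate(
    dosages: np.ndarray,
    panel: ParentalPanel,
    m1: float,
    m2: float,
    clamp: float,
    info_kind: str,
    sample_id: str,
    on_degenerate: Literal["raise", "nan"],
) -> AdmixtureEstimate:
    d = np.asarray(dosages, dtype=float)
    n_used = int(np.sum(~np.isnan(d)))
    ll = total_loglik(d, panel, m1, m2, clamp)
    try:
        var = invert_information(
            information_matrix(d, panel, m1, m2, clamp, kind=info_kind)
        )
    except DegenerateInformationError:
        if on_degenerate == "raise":
            raise
        warnings.warn(
            f"degenerate information for sample {sample_id!r}; variances set to NaN",
            stacklevel=2,
        )
        var = dict.fromkeys(
            ("v_m1", "v_m2", "cov_m1m2", "v_m3", "se_m1", "se_m2", "se_m3"), float("nan")
        )
    # m1 and m2 are grid multiples; snap m3 so 1 - m1 - m2 carries no
    # floating-point residue (e.g. 1.7e-18 instead of 0 at a vertex)
    m3 = round(1.0 - m1 - m2, 12)
    return AdmixtureEstimate(
        m1=m1, m2=m2, m3=m3, n_snps_used=n_used, loglik=ll,
        sample_id=sample_id, **var,
    )


def estimate_admixture(
    dosages: np.ndarray,
    panel: ParentalPanel,
    grid_step: float = DEFAULT_GRID_STEP,
    mode: Literal["exact-grid", "coarse-to-fine"] = "coarse-to-fine",
    clamp: float = DEFAULT_CLAMP,
    info: Literal["expected", "observed"] = "expected",
    sample_id: str = "",
    on_degenerate: Literal["raise", "nan"] = "raise",
) -> AdmixtureEstimate:
    """Grid maximum-likelihood estimate of (m1, m2, m3) for one individual.

    ``exact-grid`` evaluates every lattice point of the simplex at
    ``grid_step``; ``coarse-to-fine`` (default) first scans a 0.01 lattice
    and then refines at ``grid_step`` in a +/-0.02 box around the coarse
    maximum — it returns the same lattice point as the exhaustive scan.
    Grid ties resolve to the smallest m1, then smallest m2 (with a warning).
    """
    d = np.asarray(dosages, dtype=float)
    if not (~np.isnan(d)).any():
        raise NoDataError("all genotypes are missing for this individual")
    if mode == "exact-grid" or grid_step >= COARSE_STEP:
        m1s, m2s = simplex_grid(grid_step)
        ll = _grid_loglik(m1s, m2s, panel, d, clamp)[:, 0]
        best = int(np.argmax(ll))
        _warn_on_tie(ll, best, sample_id)
        m1, m2 = float(m1s[best]), float(m2s[best])
    elif mode == "coarse-to-fine":
        m1c, m2c = _coarse_to_fine(panel, d[None, :], grid_step, clamp)
        m1, m2 = float(m1c[0]), float(m2c[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _finish_estimate(d, panel, m1, m2, clamp, info, sample_id, on_degenerate)


def _warn_on_tie(ll: np.ndarray, best: int, sample_id: str) -> None:
    ties = np.sum(ll == ll[best])
    if ties > 1:
        logger.warning(
            "%d grid points tie at the maximum likelihood for sample %r; "
            "taking smallest m1, then smallest m2",
            ties, sample_id,
        )


def _coarse_to_fine(
    panel: ParentalPanel, D: np.ndarray, grid_step: float, clamp: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage grid argmax for a batch of individuals (rows of D)."""
    m1s, m2s = simplex_grid(COARSE_STEP)
    ll = _grid_loglik(m1s, m2s, panel, D, clamp)
    best = np.argmax(ll, axis=0)
    out1 = np.empty(D.shape[0])
    out2 = np.empty(D.shape[0])
    for i in range(D.shape[0]):
        f1, f2 = _box_grid(m1s[best[i]], m2s[best[i]], REFINE_HALFWIDTH, grid_step)
        fll = _grid_loglik(f1, f2, panel, D[i], clamp)[:, 0]
        k = int(np.argmax(fll))
        out1[i], out2[i] = f1[k], f2[k]
    return out1, out2


def estimate_cohort(
    geno: GenotypeMatrix,
    grid_step: float = DEFAULT_GRID_STEP,
    mode: Literal["exact-grid", "coarse-to-fine"] = "coarse-to-fine",
    clamp: float = DEFAULT_CLAMP,
    info: Literal["expected", "observed"] = "expected",
    on_degenerate: Literal["raise", "nan"] = "nan",
) -> list[AdmixtureEstimate]:
    """Estimate every individual of a genotype matrix.

    The coarse grid stage is evaluated for all individuals in one batched
    matrix product, which is what makes cohort-scale experiments fast; the
    per-individual refinement and information matrices follow.  Individuals
    with degenerate information get NaN variances by default (with a
    warning) so one pathological sample does not abort a cohort run.
    """
    panel = geno.panel
    D = geno.dosages
    if mode == "exact-grid" or grid_step >= COARSE_STEP:
        return [
            estimate_admixture(
                D[i], panel, grid_step, "exact-grid", clamp, info,
                sample_id=geno.sample_ids[i], on_degenerate=on_degenerate,
            )
            for i in range(geno.n_samples)
        ]
    m1, m2 = _coarse_to_fine(panel, D, grid_step, clamp)
    return [
        _finish_estimate(
            D[i], panel, float(m1[i]), float(m2[i]), clamp, info,
            geno.sample_ids[i], on_degenerate,
        )
        for i in range(geno.n_samples)
    ]
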