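"""Model projection and habitat-stratified population estimation.

Both fitted models are projected onto a table of projection sites; per
habitat stratum the possible population size is Nh = x̄h · Ph · Ah, where
x̄h is the mean predicted abundance over predicted-present sites (ind m^-2),
Ph the predicted prevalence, and Ah the areal extent (m^2).  Biomass follows
from a length-weight power law applied to the habitat's shell-length
class frequencies.  Uncertainties are percentile bootstrap intervals from
resampling projection sites within habitat (Ah held fixed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import predict_abundance
from .covariates import attenuate_exposure, substitute_marina_exposure
from .occurrence import predict_occurrence

GRAMS_PER_TONNE = 1e6


@dataclass(frozen=True)
class LengthWeightModel:
    """Allometric length-weight law W(L) = a * L^b (L in mm, W in g)."""

    a: float
    b: float
    anchors: tuple[tuple[float, float], ...] = ()

    def weight(self, length_mm) -> np.ndarray:
        return self.a * np.asarray(length_mm, dtype=float) ** self.b


def lw_calibrate(anchors) -> LengthWeightModel:
    """Calibrate the power law from (length mm, weight g) anchor pairs.

    Two anchors solve the 2x2 log-log system exactly
    (b = ln(W2/W1)/ln(L2/L1)); more anchors are fit by least squares on the
    log-log scale.  The default anchors used elsewhere in the package are
    the two size-class masses (62.5 mm ~ 40 g, 107.5 mm ~ 140 g); the
    underlying field regression is unpublished, so this two-point
    calibration is a documented approximation, overridable by config.
    """
    anchors = [(float(l), float(w)) for l, w in anchors]
    if len(anchors) < 2:
        raise ValueError("need at least 2 (length, weight) anchors")
    lengths = np.array([l for l, _ in anchors])
    weights = np.array([w for _, w in anchors])
    if np.any(lengths <= 0) or np.any(weights <= 0):
        raise ValueError("lengths and weights must be positive")
    if len(np.unique(lengths)) < len(lengths):
        raise ValueError("anchor lengths must be distinct")
    if len(anchors) == 2:
        (l1, w1), (l2, w2) = anchors
        b = np.log(w2 / w1) / np.log(l2 / l1)
        a = w1 / l1**b
    else:
        b, loga = np.polyfit(np.log(lengths), np.log(weights), 1)
        a = np.exp(loga)
    return LengthWeightModel(a=float(a), b=float(b), anchors=tuple(anchors))


DEFAULT_LW_ANCHORS = ((62.5, 40.0), (107.5, 140.0))


def length_class_frequencies(lengths_mm, bin_width: float = 5.0) -> pd.Series:
    """Bin shell lengths into ``bin_width``-mm size classes.

    Returns relative frequencies indexed by class midpoint (mm), summing to 1.
    """
    lengths = np.asarray(lengths_mm, dtype=float)
    if lengths.size == 0:
        raise ValueError("need at least one length")
    edges = np.arange(0.0, lengths.max() + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2.0
    keep = counts > 0
    return pd.Series(counts[keep] / counts.sum(), index=mids[keep], name="frequency")


def project(
    ensemble,
    abundance_model,
    projection_sites: pd.DataFrame,
    covariate_config=None,
) -> pd.DataFrame:
    """Project occurrence and conditional abundance onto projection sites.

    Marina exposures are first run through the sheltered-marina substitution,
    then all exposures are depth-attenuated; occurrence probability and the
    cutoff classification come from the ensemble, and possible abundance is
    predicted only where presence is predicted (absent sites carry NaN).
    """
    from .covariates import CovariateConfig

    cfg = covariate_config or CovariateConfig()
    known = {"marina", "natural", "natural_rocky", "pier"}
    bad = set(projection_sites["habitat"].unique()) - known
    if bad:
        raise ValueError(f"unknown habitat type(s): {sorted(bad)}")

    out = projection_sites.copy()
    exposure = out["exposure"].to_numpy(dtype=float).copy()
    is_marina = (out["habitat"] == "marina").to_numpy()
    if is_marina.any():
        exposure[is_marina] = substitute_marina_exposure(
            exposure[is_marina], cfg.exposure_substitution_threshold
        )
    depth = out["depth"].to_numpy(dtype=float) if "depth" in out else 0.0
    out["exposure"] = attenuate_exposure(exposure, depth, cfg.attenuation_k)

    occ = predict_occurrence(ensemble, out)
    out["probability"] = occ["probability"].to_numpy()
    out["presence"] = occ["presence"].to_numpy()
    abund = np.full(len(out), np.nan)
    present = out["presence"].to_numpy()
    if present.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # extrapolation warning already possible above
            abund[present] = predict_abundance(abundance_model, out.loc[present])
    out["possible_abundance"] = abund
    return out


def population_size(mean_abundance: float, invaded_area_m2: float) -> float:
    """Possible population size: mean abundance (ind m^-2) x invaded area (m^2).

    The second argument is Ph*Ah (or Ah with prevalence folded in); the
    product is linear in each argument.
    """
    if mean_abundance < 0 or invaded_area_m2 < 0:
        raise ValueError("arguments must be >= 0")
    return float(mean_abundance) * float(invaded_area_m2)


def biomass(
    n_individuals: float,
    length_frequencies: pd.Series,
    lw: LengthWeightModel,
) -> tuple[float, pd.Series]:
    """Possible biomass (tonnes live wet weight) and per-class contributions.

    Bh = Nh * sum_c f_c * W(midpoint_c), converted g -> t.  The class
    contributions partition Bh exactly.
    """
    freqs = length_frequencies.to_numpy(dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError("length-class frequencies must sum to 1")
    mids = length_frequencies.index.to_numpy(dtype=float)
    per_class = n_individuals * freqs * lw.weight(mids) / GRAMS_PER_TONNE
    contributions = pd.Series(per_class, index=length_frequencies.index,
                              name="biomass_t")
    return float(per_class.sum()), contributions


@dataclass
class HabitatEstimate:
    habitat: str
    n_sites: int
    mean_abundance: float      # x̄h over predicted-present sites, ind m^-2
    prevalence: float          # Ph
    area_m2: float             # Ah
    population: float          # Nh = x̄h Ph Ah
    biomass_t: float           # Bh
    ci_mean_abundance: tuple[float, float] = (np.nan, np.nan)
    ci_population: tuple[float, float] = (np.nan, np.nan)
    ci_biomass: tuple[float, float] = (np.nan, np.nan)
    length_contributions: pd.Series = field(default=None, repr=False)


def _stratum_stats(present: np.ndarray, abund: np.ndarray,
                   area: float) -> tuple[float, float, float]:
    ph = float(present.mean()) if len(present) else 0.0
    xbar = float(abund[present].mean()) if present.any() else 0.0
    return xbar, ph, population_size(xbar, ph * area)


def bootstrap_ci(
    values,
    statistic,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for ``statistic`` over rows of ``values``.

    Returns (point, lower, upper); the point estimate is the plug-in value
    on the original sample.  A single row gives a degenerate interval with a
    warning.
    """
    arr = np.asarray(values)
    n = arr.shape[0]
    point = float(statistic(arr))
    if n < 2:
        warnings.warn("single observation: degenerate bootstrap interval", stacklevel=2)
        return point, point, point
    rng = np.random.default_rng(seed)
    stats = np.array([
        statistic(arr[rng.integers(0, n, size=n)]) for _ in range(n_boot)
    ])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)


def estimate_habitat(
    projected: pd.DataFrame,
    habitat: str,
    area_m2: float,
    length_frequencies: pd.Series,
    lw: LengthWeightModel,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> HabitatEstimate:
    """Habitat-stratified possible population and biomass with bootstrap CIs.

    ``projected`` is the stratum's slice of the projection output.  Sites
    are resampled with replacement; x̄h, Ph, Nh and Bh are recomputed per
    resample while Ah and the length-class frequencies stay fixed.
    """
    present = projected["presence"].to_numpy()
    abund = projected["possible_abundance"].to_numpy(dtype=float)
    xbar, ph, nh = _stratum_stats(present, abund, area_m2)
    mean_weight_g = float((length_frequencies.to_numpy()
                           * lw.weight(length_frequencies.index.to_numpy())).sum())
    bh, contrib = biomass(nh, length_frequencies, lw)

    n = len(projected)
    if n < 2:
        warnings.warn("single site in stratum: degenerate bootstrap interval",
                      stacklevel=2)
        return HabitatEstimate(habitat, n, xbar, ph, area_m2, nh, bh,
                               (xbar, xbar), (nh, nh), (bh, bh), contrib)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 2))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        x_i, _, n_i = _stratum_stats(present[idx], abund[idx], area_m2)
        boot[i] = (x_i, n_i)
    alpha = (1.0 - level) / 2.0
    ci_x = tuple(np.quantile(boot[:, 0], [alpha, 1 - alpha]))
    ci_n = tuple(np.quantile(boot[:, 1], [alpha, 1 - alpha]))
    ci_b = tuple(v * mean_weight_g / GRAMS_PER_TONNE for v in ci_n)
    return HabitatEstimate(
        habitat=habitat, n_sites=n, mean_abundance=xbar, prevalence=ph,
        area_m2=area_m2, population=nh, biomass_t=bh,
        ci_mean_abundance=(float(ci_x[0]), float(ci_x[1])),
        ci_population=(float(ci_n[0]), float(ci_n[1])),
        ci_biomass=(float(ci_b[0]), float(ci_b[1])),
        length_contributions=contrib,
    )


def per_unit_area(est_a: HabitatEstimate, est_b: HabitatEstimate) -> dict:
    """Abundance and biomass per m^2 of *total* habitat, and their a:b ratios.

    Per-unit-area abundance is x̄h * Ph (equivalently Nh / Ah) and biomass is
    Bh / Ah; the ratios are invariant to a common rescaling of both areas.
    """
    for e in (est_a, est_b):
        if e.area_m2 <= 0:
            raise ValueError("areal extent must be > 0")
    abund_a, abund_b = est_a.mean_abundance * est_a.prevalence, est_b.mean_abundance * est_b.prevalence
    bio_a, bio_b = est_a.biomass_t / est_a.area_m2, est_b.biomass_t / est_b.area_m2
    return {
        "abundance_per_m2": {est_a.habitat: abund_a, est_b.habitat: abund_b},
        "biomass_t_per_m2": {est_a.habitat: bio_a, est_b.habitat: bio_b},
        "abundance_ratio": abund_a / abund_b if abund_b > 0 else np.inf,
        "biomass_ratio": bio_a / bio_b if bio_b > 0 else np.inf,
    }


def estimates_table(estimates: list[HabitatEstimate]) -> pd.DataFrame:
    """Summary table mirroring the headline columns: prevalence %, invaded
    area km^2, possible population (x 10^6) and biomass (t), with CIs."""
    rows = []
    for e in estimates:
        rows.append({
            "habitat": e.habitat,
            "n_sites": e.n_sites,
            "prevalence_pct": 100.0 * e.prevalence,
            "invaded_area_km2": e.prevalence * e.area_m2 / 1e6,
            "mean_abundance": e.mean_abundance,
            "mean_abundance_lo": e.ci_mean_abundance[0],
            "mean_abundance_hi": e.ci_mean_abundance[1],
            "population_millions": e.population / 1e6,
            "population_millions_lo": e.ci_population[0] / 1e6,
            "population_millions_hi": e.ci_population[1] / 1e6,
            "biomass_t": e.biomass_t,
            "biomass_t_lo": e.ci_biomass[0],
            "biomass_t_hi": e.ci_biomass[1],
        })
    return pd.DataFrame(rows)
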