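"""Post-estimation quantities: variance partitioning, shrunken community
prevalences, area summaries, dispersion correlation and classification.

The variance partitioning coefficient (VPC) of a level is its variance share
of the total geographic variance sigma2_state + sigma2_district +
sigma2_community (the default "geographic" denominator); the optional
"latent" denominator adds pi^2/3, the level-1 variance of the latent logistic
threshold formulation.

Precision-weighted community prevalence is the empirical-Bayes shrinkage
prediction antilogit(beta0 + f_l + v_k + u_j) x 100 evaluated at posterior
means of the model residuals: posterior means of hierarchical residuals pull
small, unreliable communities toward the overall mean. A closed-form EB mode
on the empirical-logit scale is provided as an independent cross-check of the
MCMC route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import pearsonr

from .errors import InsufficientDataError, LineageError, UndefinedVpcError
from .mlm import ModelFit, NestedIndex, _collapse

__all__ = [
    "VpcResult",
    "compute_vpc",
    "precision_weighted_prevalence",
    "summarise_areas",
    "district_dispersion_correlation",
    "classify_under_empowered",
    "cross_tabulate_quadrants",
]

LATENT_LEVEL1_VARIANCE = np.pi**2 / 3.0


@dataclass
class VpcResult:
    """Per-level variance shares in percent."""

    state: float
    district: float
    community: float
    mode: str = "geographic"

    def as_dict(self) -> dict:
        return {"state": self.state, "district": self.district, "community": self.community}


def compute_vpc(variances, mode: str = "geographic") -> VpcResult:
    """Partition the geographic variance across state/district/community.

    ``variances`` is a (sigma2_state, sigma2_district, sigma2_community)
    triple or a :class:`~swpergeo.mlm.VarianceComponents` (posterior means
    are used). Geographic mode divides by the sum of the three variances, so
    the shares always total 100%; latent mode adds pi^2/3 to the denominator.
    """
    if hasattr(variances, "means"):
        s2f, s2v, s2u = variances.means()
    else:
        s2f, s2v, s2u = variances
    for name, val in (("state", s2f), ("district", s2v), ("community", s2u)):
        if not np.isfinite(val) or val < 0:
            raise ValueError(f"sigma2_{name} must be finite and >= 0, got {val}")
    total = s2f + s2v + s2u
    if mode == "geographic":
        if total == 0:
            raise UndefinedVpcError("all geographic variances are zero; VPC undefined")
        denom = total
    elif mode == "latent":
        denom = total + LATENT_LEVEL1_VARIANCE
    else:
        raise ValueError(f"unknown VPC mode {mode!r}")
    return VpcResult(
        state=100.0 * s2f / denom,
        district=100.0 * s2v / denom,
        community=100.0 * s2u / denom,
        mode=mode,
    )


def precision_weighted_prevalence(
    fit: ModelFit | None,
    index: NestedIndex,
    records: pd.DataFrame | None = None,
    outcome: str = "y",
    method: str = "posterior",
) -> pd.DataFrame:
    """Shrunken prevalence (%) of the outcome for every community in the index.

    ``method='posterior'`` (default) uses the MCMC posterior means:
    antilogit(beta0_hat + f_hat + v_hat + u_hat) x 100. ``method='eb_linear'``
    is the closed-form empirical-Bayes cross-check on the empirical-logit
    scale: the community effect is shrunk by the variance-ratio weight
    w_j = sigma2_community / (sigma2_community + s2_j), where s2_j is the
    sampling variance of the community's empirical logit; it requires
    ``records`` for the raw counts.

    Returns community_id, district_id, state_id, n_women, raw_prev_pct,
    prevalence_pct.
    """
    J = index.n_communities
    lineage = pd.DataFrame(
        {
            "community_id": index.community_labels,
            "district_id": index.district_labels[index.community_district],
            "state_id": index.state_labels[index.community_state],
        }
    )
    if records is not None:
        y_j, n_j = _collapse(records, index, outcome)
        raw = np.divide(y_j, n_j, out=np.full(J, np.nan), where=n_j > 0)
    else:
        y_j = n_j = None
        raw = np.full(J, np.nan)

    if method == "posterior":
        if fit is None:
            raise ValueError("posterior method needs a ModelFit")
        res = fit.residuals
        if len(res["community"]) != J:
            raise LineageError(
                f"fit has {len(res['community'])} communities but index has {J}"
            )
        if not np.array_equal(res["community"]["label"].to_numpy(), index.community_labels):
            raise LineageError("fit community labels do not match the index")
        u = res["community"]["post_mean"].to_numpy()
        v = res["district"]["post_mean"].to_numpy()[index.community_district]
        f = res["state"]["post_mean"].to_numpy()[index.community_state]
        eta = fit.beta0.mean + u + v + f
    elif method == "eb_linear":
        if records is None:
            raise ValueError("eb_linear method needs the records for raw counts")
        p_t = (y_j + 0.5) / (n_j + 1.0)
        lz = logit(p_t)
        grand = float(np.average(lz, weights=n_j))
        s2_j = 1.0 / (n_j * np.clip(p_t * (1 - p_t), 1e-10, None))
        if fit is not None:
            s2u = fit.variances.sigma2_community.mean
        else:
            resid = lz - grand
            s2u = max(float(np.var(resid, ddof=1) - np.mean(s2_j)), 1e-6)
        w = s2u / (s2u + s2_j)
        eta = grand + w * (lz - grand)
    else:
        raise ValueError(f"unknown method {method!r}")

    out = lineage.copy()
    out["n_women"] = n_j.astype(int) if n_j is not None else 0
    out["raw_prev_pct"] = 100.0 * raw
    out["prevalence_pct"] = 100.0 * expit(eta)
    return out


def summarise_areas(estimates: pd.DataFrame, level: str) -> pd.DataFrame:
    """Unweighted mean/SD/min/max of community prevalences per state or district.

    ``level`` is ``'state'`` or ``'district'``. SD is the sample (n-1)
    standard deviation; areas with a single community get SD 0.
    """
    if level not in ("state", "district"):
        raise ValueError(f"level must be 'state' or 'district', got {level!r}")
    key = f"{level}_id"
    g = estimates.groupby(key, sort=True)["prevalence_pct"]
    out = g.agg(
        mean_prev_pct="mean",
        sd_prev_pct=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
        min_prev_pct="min",
        max_prev_pct="max",
        n_communities="size",
    ).reset_index()
    if level == "district":
        parents = estimates.drop_duplicates("district_id")[["district_id", "state_id"]]
        out = out.merge(parents, on="district_id", how="left")
    return out


def district_dispersion_correlation(summaries: pd.DataFrame) -> dict:
    """Pearson r between district mean prevalence and within-district SD.

    Districts with a single community (undefined dispersion) are excluded and
    counted; fewer than 3 usable districts raises
    :class:`InsufficientDataError`. If either variable has zero variance the
    correlation is flagged undefined instead of raising.
    """
    usable = summaries[summaries["n_communities"] >= 2]
    n_excluded = len(summaries) - len(usable)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"only {len(usable)} districts with >= 2 communities; need >= 3"
        )
    x = usable["mean_prev_pct"].to_numpy()
    y = usable["sd_prev_pct"].to_numpy()
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return {
            "r": None,
            "p_value": None,
            "n_districts": len(usable),
            "n_excluded": n_excluded,
            "flag": "zero-variance",
        }
    r, p = pearsonr(x, y)
    return {
        "r": float(r),
        "p_value": float(p),
        "n_districts": len(usable),
        "n_excluded": n_excluded,
        "flag": None,
    }


def classify_under_empowered(
    estimates: pd.DataFrame,
    national_mean: float | None = None,
    threshold_fraction: float = 0.9,
    weight_by_women: bool = False,
) -> dict:
    """Flag under-empowered communities and tally districts dominated by them.

    A community is under-empowered when its prevalence is *equal to or
    higher than* the national mean (the boundary community is flagged). The
    national mean defaults to the unweighted mean over communities of the
    shrunken estimates; ``weight_by_women`` switches to a woman-weighted
    mean. A district counts toward the tally when *strictly more than*
    ``threshold_fraction`` of its communities are under-empowered.

    Returns flags (per community), per-district fractions, the tally and the
    national mean used.
    """
    prev = estimates["prevalence_pct"].to_numpy(dtype=float)
    if national_mean is None:
        if weight_by_women:
            national_mean = float(np.average(prev, weights=estimates["n_women"]))
        else:
            national_mean = float(np.mean(prev))
    flags = estimates[["community_id", "district_id", "state_id"]].copy()
    flags["under_empowered"] = (prev >= national_mean).astype(int)
    frac = (
        flags.groupby("district_id", sort=True)["under_empowered"]
        .mean()
        .rename("fraction_under_empowered")
        .reset_index()
    )
    tally = int((frac["fraction_under_empowered"] > threshold_fraction).sum())
    return {
        "national_mean_pct": national_mean,
        "flags": flags,
        "district_fractions": frac,
        "n_districts_over_threshold": tally,
        "threshold_fraction": threshold_fraction,
    }


def cross_tabulate_quadrants(
    summaries: pd.DataFrame,
    mean_of_means: float | None = None,
    mean_of_sds: float | None = None,
) -> dict:
    """2x2 counts of districts by (prevalence vs all-India mean) x (SD vs its mean).

    Boundaries are assigned by >= on both axes. National means default to the
    unweighted means of the district summaries themselves.
    """
    means = summaries["mean_prev_pct"].to_numpy(dtype=float)
    sds = summaries["sd_prev_pct"].to_numpy(dtype=float)
    if mean_of_means is None:
        mean_of_means = float(np.mean(means))
    if mean_of_sds is None:
        mean_of_sds = float(np.mean(sds))
    above_prev = means >= mean_of_means
    above_sd = sds >= mean_of_sds
    return {
        "mean_prev_pct": mean_of_means,
        "mean_sd_pct": mean_of_sds,
        "below_prev_below_sd": int(np.sum(~above_prev & ~above_sd)),
        "below_prev_above_sd": int(np.sum(~above_prev & above_sd)),
        "above_prev_below_sd": int(np.sum(above_prev & ~above_sd)),
        "above_prev_above_sd": int(np.sum(above_prev & above_sd)),
    }
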