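"""Synthetic four-level nested survey data with known ground truth.

Generates woman-level records nested in communities (survey PSUs), districts
and states, mirroring the structure of India's NFHS-5 individual recode:
36 states, ~720 districts, ~9100 communities and ~77 000 analytic women.
Binary low-empowerment outcomes are drawn from the four-level random-intercept
logit, item responses from a configurable latent-propensity model, and
eligibility flags (union status, module selection, item missingness) are
planted so the downstream filter cascade can be exercised end to end.

Ground-truth parameters (intercept, the three latent-scale variances, realised
random effects) are retained alongside the records, so every downstream
estimator can be checked against what actually generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .errors import FixtureParseError, InvalidSpecError, SwperGeoError

__all__ = [
    "ItemModel",
    "PopulationSpec",
    "SyntheticSurvey",
    "generate_hierarchy",
    "simulate_binary_outcomes",
    "simulate_item_responses",
    "write_fixture",
    "read_fixture",
]

# Cascade of the source survey: 724 115 women aged 15-49, of whom 211 707 were
# not currently married/in union, 435 498 not selected for the relevant
# question modules, and 227 had missing index items, leaving 76 683 analytic
# women. Rates are expressed as fractions of the initial sample removed at
# each sequential step, so the expected surviving fraction is 76 683/724 115.
NFHS5_TOTAL_WOMEN = 724_115
NFHS5_EXCLUSION_RATES = (
    211_707 / NFHS5_TOTAL_WOMEN,
    435_498 / NFHS5_TOTAL_WOMEN,
    227 / NFHS5_TOTAL_WOMEN,
)

# Item layout: 5 attitude-to-violence items, 6 social-independence items,
# 3 decision-making items (14 total).
N_ITEMS = 14
DOMAIN_SLICES = {
    "attitude_to_violence": slice(0, 5),
    "social_independence": slice(5, 11),
    "decision_making": slice(11, 14),
}


@dataclass(frozen=True)
class ItemModel:
    """Latent-propensity model linking empowerment to the 14 item responses.

    Each woman has a latent empowerment propensity equal to minus her random-
    effect contribution (communities with high low-empowerment propensity are
    less empowered) plus idiosyncratic noise. Each item is an ordered
    categorical obtained by thresholding ``loading * latent + noise`` at
    standard-normal quantiles, so the codebook's weighted sums recover a score
    correlated with the latent propensity.

    This is deliberately a stand-in: the source survey publishes no generative
    model for the items, only the scoring path needs to be exercised.
    """

    loading: float = 0.75
    woman_noise_sd: float = 1.0
    # categories per item: violence items are yes/no, social-independence
    # items are coarse ordinal grades, decision items are 3-way
    item_categories: tuple[int, ...] = (2,) * 5 + (4,) * 6 + (3,) * 3

    def validate(self) -> None:
        if not (0.0 <= self.loading <= 1.0):
            raise InvalidSpecError(f"item loading must be in [0, 1], got {self.loading}")
        if self.woman_noise_sd < 0 or not np.isfinite(self.woman_noise_sd):
            raise InvalidSpecError("woman_noise_sd must be finite and >= 0")
        if len(self.item_categories) != N_ITEMS:
            raise InvalidSpecError(f"need {N_ITEMS} item category counts")
        if any(c < 2 for c in self.item_categories):
            raise InvalidSpecError("each item needs >= 2 categories")


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters of the synthetic four-level population.

    Defaults are the study conditions of the national survey analysis this
    package mirrors: 36 states, 720 districts (20 per state), an average of
    ~12.6 communities per district (9104 communities in expectation) and
    ~79.5 sampled women per community (~724 115 in expectation), of whom the
    exclusion cascade retains ~8.4 per community (~76 683 analytic women).
    The intercept is anchored at a 29.2% national prevalence of low
    empowerment and the latent-scale variances (state, district, community)
    are (0.86, 0.23, 0.97) — the attitude-to-violence variance components.

    ``districts_per_state`` etc. accept an int, a per-parent list, or a
    ``("poisson", mean)`` pair (draws are clipped to >= 1).
    """

    n_states: int = 36
    districts_per_state: int | tuple | list = 20
    communities_per_district: int | tuple | list = ("poisson", 12.644)
    women_per_community: int | tuple | list = ("poisson", 79.538)
    beta0: float = float(logit(0.292))
    sigma2_state: float = 0.86
    sigma2_district: float = 0.23
    sigma2_community: float = 0.97
    item_model: ItemModel = field(default_factory=ItemModel)
    exclusion_rates: tuple[float, float, float] = NFHS5_EXCLUSION_RATES
    seed: int = 0

    def validate(self) -> None:
        if self.n_states < 1:
            raise InvalidSpecError("n_states must be >= 1")
        for name in ("sigma2_state", "sigma2_district", "sigma2_community"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidSpecError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.beta0):
            raise InvalidSpecError("beta0 must be finite")
        r = self.exclusion_rates
        if len(r) != 3 or any(not (0 <= x < 1) for x in r) or sum(r) >= 1:
            raise InvalidSpecError(
                "exclusion rates must each be in [0,1) and jointly sum to < 1"
            )
        self.item_model.validate()


@dataclass
class SyntheticSurvey:
    """Generated records plus the ground truth that produced them.

    ``records`` is one row per woman (nesting keys, outcome, items, flags,
    true outcome probability). ``truth`` holds the spec echo and the realised
    random effects per unit at each level.
    """

    records: pd.DataFrame
    truth: dict

    @property
    def spec(self) -> PopulationSpec:
        return self.truth["spec"]


def _draw_counts(setting, n_parents: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve an int / list / ('poisson', mean) count setting to per-parent counts."""
    if isinstance(setting, (int, np.integer)):
        if setting < 1:
            raise InvalidSpecError(f"counts must be >= 1, got {setting}")
        return np.full(n_parents, int(setting), dtype=int)
    if isinstance(setting, (tuple, list)) and len(setting) == 2 and setting[0] == "poisson":
        lam = float(setting[1])
        if not np.isfinite(lam) or lam <= 0:
            raise InvalidSpecError(f"poisson mean must be positive, got {lam}")
        return np.maximum(1, rng.poisson(lam, size=n_parents))
    counts = np.asarray(setting, dtype=int)
    if counts.shape != (n_parents,) or (counts < 1).any():
        raise InvalidSpecError(
            f"per-parent count list must have length {n_parents} with entries >= 1"
        )
    return counts


def generate_hierarchy(spec: PopulationSpec) -> SyntheticSurvey:
    """Build the nested state/district/community/woman frame and draw random effects.

    Random effects at each level come from dedicated substreams of the root
    seed (f ~ N(0, sigma2_state), v ~ N(0, sigma2_district),
    u ~ N(0, sigma2_community)), so changing the number of women per community
    leaves the unit effects untouched.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    (s_state, s_district, s_community, s_counts) = [
        np.random.default_rng(c) for c in ss.spawn(7)[:4]
    ]

    n_states = spec.n_states
    d_per_s = _draw_counts(spec.districts_per_state, n_states, s_counts)
    n_districts = int(d_per_s.sum())
    c_per_d = _draw_counts(spec.communities_per_district, n_districts, s_counts)
    n_communities = int(c_per_d.sum())
    w_per_c = _draw_counts(spec.women_per_community, n_communities, s_counts)
    n_women = int(w_per_c.sum())

    f = s_state.normal(0.0, np.sqrt(spec.sigma2_state), size=n_states)
    v = s_district.normal(0.0, np.sqrt(spec.sigma2_district), size=n_districts)
    u = s_community.normal(0.0, np.sqrt(spec.sigma2_community), size=n_communities)

    district_state = np.repeat(np.arange(n_states), d_per_s)
    community_district = np.repeat(np.arange(n_districts), c_per_d)
    woman_community = np.repeat(np.arange(n_communities), w_per_c)

    state_ids = np.array([f"S{i + 1:02d}" for i in range(n_states)])
    district_ids = np.array(
        [
            f"{state_ids[s]}D{j + 1:03d}"
            for s, j in zip(district_state, _within_parent_rank(district_state))
        ]
    )
    community_ids = np.array(
        [
            f"{district_ids[d]}C{j + 1:03d}"
            for d, j in zip(community_district, _within_parent_rank(community_district))
        ]
    )

    comm_of_woman = woman_community
    dist_of_woman = community_district[comm_of_woman]
    state_of_woman = district_state[dist_of_woman]
    eta = spec.beta0 + u[comm_of_woman] + v[dist_of_woman] + f[state_of_woman]

    records = pd.DataFrame(
        {
            "state_id": state_ids[state_of_woman],
            "district_id": district_ids[dist_of_woman],
            "community_id": community_ids[comm_of_woman],
            "woman_id": [f"W{i + 1:07d}" for i in range(n_women)],
            "p_true": expit(eta),
        }
    )

    truth = {
        "spec": spec,
        "state_effects": dict(zip(state_ids.tolist(), f.tolist())),
        "district_effects": dict(zip(district_ids.tolist(), v.tolist())),
        "community_effects": dict(zip(community_ids.tolist(), u.tolist())),
    }
    return SyntheticSurvey(records=records, truth=truth)


def _within_parent_rank(parent_codes: np.ndarray) -> np.ndarray:
    """0-based running index of each unit within its (sorted, contiguous) parent."""
    if len(parent_codes) == 0:
        return np.array([], dtype=int)
    starts = np.r_[0, np.flatnonzero(np.diff(parent_codes)) + 1]
    sizes = np.diff(np.r_[starts, len(parent_codes)])
    return np.arange(len(parent_codes)) - np.repeat(starts, sizes)


def simulate_binary_outcomes(survey: SyntheticSurvey) -> SyntheticSurvey:
    """Draw each woman's low-empowerment indicator Y ~ Bernoulli(antilogit(eta)).

    eta = beta0 + u + v + f is the woman's true linear predictor, already
    materialised as ``p_true`` by :func:`generate_hierarchy`.
    """
    if "p_true" not in survey.records:
        raise SwperGeoError("hierarchy must be generated before outcomes")
    rng = np.random.default_rng(np.random.SeedSequence(survey.spec.seed).spawn(7)[4])
    rec = survey.records.copy()
    rec["y"] = (rng.random(len(rec)) < rec["p_true"].to_numpy()).astype(int)
    return SyntheticSurvey(records=rec, truth=survey.truth)


def simulate_item_responses(survey: SyntheticSurvey) -> SyntheticSurvey:
    """Generate the 14 ordinal item responses and plant the exclusion flags.

    A woman's latent empowerment propensity is minus her standardised random-
    effect contribution plus N(0, woman_noise_sd) noise; each item thresholds
    ``loading * latent + sqrt(1 - loading^2) * noise`` at equal-probability
    standard-normal cut points. Exclusion flags (not in union, not selected
    for the question modules, item missingness) are drawn independently per
    woman with conditional probabilities chosen so each cascade step removes
    the configured fraction of the initial sample; flagged-missing women get
    one randomly chosen item blanked.
    """
    spec = survey.spec
    im = spec.item_model
    if im is None:
        raise InvalidSpecError("item_model missing from spec")
    im.validate()
    rec = survey.records.copy()
    n = len(rec)
    children = np.random.SeedSequence(spec.seed).spawn(7)
    rng_items = np.random.default_rng(children[5])
    rng_excl = np.random.default_rng(children[6])

    # latent empowerment propensity, standardised on its theoretical scale
    eta_re = logit(rec["p_true"].to_numpy()) - spec.beta0
    total_var = (
        spec.sigma2_state + spec.sigma2_district + spec.sigma2_community
    ) + im.woman_noise_sd**2
    noise = rng_items.normal(0.0, im.woman_noise_sd, size=n)
    if total_var > 0:
        latent = -(eta_re + noise) / np.sqrt(total_var)
    else:
        latent = np.zeros(n)

    resid_sd = np.sqrt(max(0.0, 1.0 - im.loading**2))
    from scipy.stats import norm

    for i, n_cat in enumerate(im.item_categories):
        item_latent = im.loading * latent + resid_sd * rng_items.standard_normal(n)
        cuts = norm.ppf(np.arange(1, n_cat) / n_cat)
        rec[f"item_{i + 1}"] = np.searchsorted(cuts, item_latent).astype(float)

    r1, r2, r3 = spec.exclusion_rates
    q1 = r1
    q2 = r2 / (1 - r1) if r1 < 1 else 0.0
    q3 = r3 / (1 - r1 - r2) if (r1 + r2) < 1 else 0.0
    rec["in_union"] = (rng_excl.random(n) >= q1).astype(int)
    rec["module_selected"] = (rng_excl.random(n) >= q2).astype(int)
    missing = rng_excl.random(n) < q3
    which_item = rng_excl.integers(1, N_ITEMS + 1, size=n)
    for i in range(1, N_ITEMS + 1):
        mask = missing & (which_item == i)
        if mask.any():
            rec.loc[mask, f"item_{i}"] = np.nan
    return SyntheticSurvey(records=rec, truth=survey.truth)


def generate_survey(spec: PopulationSpec) -> SyntheticSurvey:
    """Convenience: hierarchy + outcomes + items in one call."""
    return simulate_item_responses(simulate_binary_outcomes(generate_hierarchy(spec)))


# ---------------------------------------------------------------------------
# fixture I/O: CSV for the records, YAML sidecar for the ground truth


def _truth_to_yaml(truth: dict) -> str:
    spec = truth["spec"]
    payload = {
        "spec": {
            "n_states": spec.n_states,
            "districts_per_state": _jsonable(spec.districts_per_state),
            "communities_per_district": _jsonable(spec.communities_per_district),
            "women_per_community": _jsonable(spec.women_per_community),
            "beta0": float(spec.beta0),
            "sigma2_state": float(spec.sigma2_state),
            "sigma2_district": float(spec.sigma2_district),
            "sigma2_community": float(spec.sigma2_community),
            "item_model": {
                "loading": spec.item_model.loading,
                "woman_noise_sd": spec.item_model.woman_noise_sd,
                "item_categories": list(spec.item_model.item_categories),
            },
            "exclusion_rates": [float(r) for r in spec.exclusion_rates],
            "seed": int(spec.seed),
        },
        "state_effects": truth["state_effects"],
        "district_effects": truth["district_effects"],
        "community_effects": truth["community_effects"],
    }
    return yaml.safe_dump(payload, sort_keys=True)


def _jsonable(setting):
    if isinstance(setting, (int, np.integer)):
        return int(setting)
    return list(setting)


def _setting_from_yaml(raw):
    if isinstance(raw, int):
        return raw
    if isinstance(raw, list) and len(raw) == 2 and raw[0] == "poisson":
        return ("poisson", float(raw[1]))
    return list(raw)


def write_fixture(survey: SyntheticSurvey, path) -> None:
    """Write ``<path>`` (records CSV) and ``<path>.truth.yaml`` (ground truth)."""
    path = str(path)
    survey.records.to_csv(path, index=False)
    with open(path + ".truth.yaml", "w") as fh:
        fh.write(_truth_to_yaml(survey.truth))


def read_fixture(path) -> SyntheticSurvey:
    """Read a fixture written by :func:`write_fixture`; validates nesting."""
    path = str(path)
    try:
        records = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FixtureParseError(f"cannot parse records CSV {path}: {exc}") from exc
    required = {"state_id", "district_id", "community_id", "woman_id"}
    if not required.issubset(records.columns):
        raise FixtureParseError(
            f"records CSV {path} lacks key columns {sorted(required - set(records.columns))}",
            line=1,
        )
    try:
        with open(path + ".truth.yaml") as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        raise FixtureParseError(
            f"cannot parse truth sidecar for {path}: {exc}",
            line=None if mark is None else mark.line + 1,
        ) from exc
    if not isinstance(raw, dict) or "spec" not in raw:
        raise FixtureParseError(f"truth sidecar for {path} is incomplete", line=1)
    s = raw["spec"]
    try:
        spec = PopulationSpec(
            n_states=s["n_states"],
            districts_per_state=_setting_from_yaml(s["districts_per_state"]),
            communities_per_district=_setting_from_yaml(s["communities_per_district"]),
            women_per_community=_setting_from_yaml(s["women_per_community"]),
            beta0=s["beta0"],
            sigma2_state=s["sigma2_state"],
            sigma2_district=s["sigma2_district"],
            sigma2_community=s["sigma2_community"],
            item_model=ItemModel(
                loading=s["item_model"]["loading"],
                woman_noise_sd=s["item_model"]["woman_noise_sd"],
                item_categories=tuple(s["item_model"]["item_categories"]),
            ),
            exclusion_rates=tuple(s["exclusion_rates"]),
            seed=s["seed"],
        )
    except (KeyError, TypeError) as exc:
        raise FixtureParseError(f"truth sidecar for {path} is incomplete: {exc}") from exc
    truth = {
        "spec": spec,
        "state_effects": raw["state_effects"],
        "district_effects": raw["district_effects"],
        "community_effects": raw["community_effects"],
    }
    survey = SyntheticSurvey(records=records, truth=truth)
    validate_nesting(records)
    return survey


def validate_nesting(records: pd.DataFrame) -> None:
    """Check that community -> district and district -> state are functions."""
    cd = records.groupby("community_id")["district_id"].nunique()
    if (cd > 1).any():
        raise FixtureParseError(
            f"communities under multiple districts: {cd[cd > 1].index.tolist()}"
        )
    ds = records.groupby("district_id")["state_id"].nunique()
    if (ds > 1).any():
        raise FixtureParseError(
            f"districts under multiple states: {ds[ds > 1].index.tolist()}"
        )
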