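"""SWPER outcome construction: eligibility filtering, scoring, classification.

The SWPER (Survey-based Women's emPowERment index) summarises 14 survey items
into three domain scores — attitude to violence (5 items), social independence
(6 items), decision-making (3 items) — as weighted sums of recoded item
responses. Scores are standardised and cut into terciles; the bottom tercile
defines the binary primary outcome "low level of empowerment".

The default codebook shipped with the package
(``data/swper_codebook_synthetic.csv``) is a synthetic stand-in that follows
the published domain structure but not the published weights; analyses of real
survey data should supply the published codebook file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import (
    CodebookError,
    DataError,
    DegenerateDistributionError,
    SchemaError,
)

__all__ = [
    "DOMAINS",
    "ItemCodebook",
    "load_codebook",
    "default_codebook",
    "apply_filter_cascade",
    "score_domains",
    "standardise_and_classify",
]

DOMAINS = ("attitude_to_violence", "social_independence", "decision_making")
_DOMAIN_ITEM_COUNTS = {"attitude_to_violence": 5, "social_independence": 6, "decision_making": 3}
ITEM_COLUMNS = [f"item_{i}" for i in range(1, 15)]


@dataclass
class ItemCodebook:
    """Recode maps and domain weights for the 14 index items.

    ``recodes``  maps item_id -> {raw category -> recoded numeric value};
    ``weights``  maps item_id -> (domain, weight);
    ``metadata`` must carry a ``source`` entry (provenance) or scoring refuses
    to run; optional ``std_mean_<domain>`` / ``std_sd_<domain>`` entries give
    external standardisation constants.
    """

    recodes: dict[str, dict[float, float]]
    weights: dict[str, tuple[str, float]]
    metadata: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.metadata.get("source"):
            raise CodebookError(
                "codebook has no 'source' provenance entry; refusing to score"
            )
        counts = {d: 0 for d in DOMAINS}
        for item, (domain, _) in self.weights.items():
            if domain not in counts:
                raise CodebookError(f"unknown domain {domain!r} for {item}")
            counts[domain] += 1
        if counts != _DOMAIN_ITEM_COUNTS:
            raise CodebookError(
                f"domain item counts {counts} != required {_DOMAIN_ITEM_COUNTS}"
            )
        missing = [i for i in ITEM_COLUMNS if i not in self.recodes]
        if missing:
            raise CodebookError(f"items without recode entries: {missing}")

    def external_constants(self, domain: str) -> tuple[float, float] | None:
        m = self.metadata.get(f"std_mean_{domain}")
        s = self.metadata.get(f"std_sd_{domain}")
        if m is None or s is None:
            return None
        return float(m), float(s)


def load_codebook(path) -> ItemCodebook:
    """Load a codebook from columnar text with ``# key: value`` header metadata."""
    metadata: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, val = stripped.partition(":")
                metadata[key.strip()] = val.strip()
        else:
            body_start = i
            break
    table = pd.read_csv(pd.io.common.StringIO("".join(lines[body_start:])))
    required = {"item_id", "domain", "raw_value", "recoded_value", "weight"}
    if not required.issubset(table.columns):
        raise CodebookError(
            f"codebook lacks columns {sorted(required - set(table.columns))}"
        )
    recodes: dict[str, dict[float, float]] = {}
    weights: dict[str, tuple[str, float]] = {}
    for row in table.itertuples():
        recodes.setdefault(row.item_id, {})[float(row.raw_value)] = float(row.recoded_value)
        prev = weights.get(row.item_id)
        if prev is not None and prev != (row.domain, float(row.weight)):
            raise CodebookError(f"inconsistent domain/weight rows for {row.item_id}")
        weights[row.item_id] = (row.domain, float(row.weight))
    book = ItemCodebook(recodes=recodes, weights=weights, metadata=metadata)
    book.validate()
    return book


def default_codebook() -> ItemCodebook:
    """The synthetic stand-in codebook shipped with the package."""
    ref = resources.files("swpergeo.data") / "swper_codebook_synthetic.csv"
    with resources.as_file(ref) as path:
        return load_codebook(path)


def apply_filter_cascade(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the eligibility cascade and tally exclusions at each step.

    Order mirrors the survey's analytic-sample construction: (1) drop women
    not currently married/in union, (2) drop women not selected for the
    question modules, (3) drop women with any missing index item. Returns the
    eligible records and a tally dict with per-step counts.
    """
    for col in ("in_union", "module_selected"):
        if col not in records.columns:
            raise SchemaError(f"records lack required flag column {col!r}")
    missing_items = [c for c in ITEM_COLUMNS if c not in records.columns]
    if missing_items:
        raise SchemaError(f"records lack item columns {missing_items}")

    n0 = len(records)
    step1 = records[records["in_union"] == 1]
    n_union = n0 - len(step1)
    step2 = step1[step1["module_selected"] == 1]
    n_module = len(step1) - len(step2)
    complete = step2[ITEM_COLUMNS].notna().all(axis=1)
    eligible = step2[complete]
    n_missing = len(step2) - len(eligible)
    tally = {
        "input": n0,
        "excluded_not_in_union": n_union,
        "excluded_not_module_selected": n_module,
        "excluded_missing_items": n_missing,
        "eligible": len(eligible),
    }
    return eligible.copy(), tally


def score_domains(records: pd.DataFrame, codebook: ItemCodebook) -> pd.DataFrame:
    """Compute raw domain scores as weighted sums of recoded items.

    Returns a tidy frame with one row per woman per domain:
    woman_id, domain, raw_score. Raises :class:`DataError` naming the woman
    and item on any response the codebook cannot recode.
    """
    codebook.validate()
    missing = [c for c in ITEM_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"records lack item columns {missing}")

    raw = {d: np.zeros(len(records)) for d in DOMAINS}
    woman_ids = records["woman_id"].to_numpy()
    for item in ITEM_COLUMNS:
        domain, weight = codebook.weights[item]
        rmap = codebook.recodes[item]
        values = records[item].to_numpy(dtype=float)
        recoded = np.full(len(values), np.nan)
        for raw_cat, code in rmap.items():
            recoded[values == raw_cat] = code
        bad = np.isnan(recoded)
        if bad.any():
            w = woman_ids[bad][0]
            v = values[bad][0]
            raise DataError(
                f"cannot recode {item}={v!r} for woman {w!r}: not in codebook"
            )
        raw[domain] += weight * recoded

    frames = [
        pd.DataFrame({"woman_id": woman_ids, "domain": d, "raw_score": raw[d]})
        for d in DOMAINS
    ]
    return pd.concat(frames, ignore_index=True)


def standardise_and_classify(
    scores: pd.DataFrame, mode: str = "within_sample", codebook: ItemCodebook | None = None
) -> pd.DataFrame:
    """Standardise raw scores and cut them into terciles per domain.

    ``mode='within_sample'`` standardises with the analytic sample's own
    mean/SD; ``mode='external'`` uses the codebook's standardisation constants.
    Tercile boundaries sit at the empirical 33.33rd/66.67th percentile ranks;
    ties at a boundary are broken by stable rank after a pre-sort on woman key
    (first occurrence goes to the lower tercile). ``low_binary`` is 1 exactly
    for the low tercile.

    Returns woman_id, domain, raw_score, z_score, tercile, low_binary.
    """
    if mode not in ("within_sample", "external"):
        raise ValueError(f"unknown standardisation mode {mode!r}")
    out = []
    for domain, grp in scores.groupby("domain", sort=False):
        grp = grp.sort_values("woman_id", kind="stable").reset_index(drop=True)
        x = grp["raw_score"].to_numpy(dtype=float)
        if mode == "external":
            if codebook is None or codebook.external_constants(domain) is None:
                raise CodebookError(
                    f"external standardisation requested but no constants for {domain}"
                )
            m, s = codebook.external_constants(domain)
        else:
            m, s = float(np.mean(x)), float(np.std(x, ddof=0))
        if s <= 0:
            raise DegenerateDistributionError(
                f"domain {domain} has zero score SD; cannot standardise"
            )
        z = (x - m) / s

        n = len(z)
        order = np.argsort(z, kind="stable")  # stable: ties keep woman-key order
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        k1 = int(np.ceil(n / 3))
        k2 = int(np.ceil(2 * n / 3))
        tercile = np.where(rank < k1, "low", np.where(rank < k2, "medium", "high"))
        out.append(
            pd.DataFrame(
                {
                    "woman_id": grp["woman_id"],
                    "domain": domain,
                    "raw_score": x,
                    "z_score": z,
                    "tercile": tercile,
                    "low_binary": (tercile == "low").astype(int),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def attach_outcomes(records: pd.DataFrame, classes: pd.DataFrame) -> pd.DataFrame:
    """Merge per-domain low-empowerment indicators back onto the records.

    Adds one ``low_<domain>`` column per domain; rows are the eligible women.
    """
    wide = classes.pivot(index="woman_id", columns="domain", values="low_binary")
    wide.columns = [f"low_{d}" for d in wide.columns]
    return records.merge(wide, left_on="woman_id", right_index=True, how="inner")
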