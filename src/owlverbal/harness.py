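"""Expert-rating protocol: sheets, agreement, summaries, correlation.

The protocol rates every verbalized axiom on three dimensions:

* **Clarity** — 1 (clear), 2 (clear but the axiom itself is ambiguous),
  3 (not interpretable);
* **NL fidelity to axiom** — yes/no: does the sentence express the logic?
* **Axiom fidelity to domain** — 1 (agrees with the axiom), 2 (uncertain
  about concepts *or* relationships), 3 (uncertain about both).

Summaries report mean/SD of the per-item mean score across raters, the
percentage of "yes" votes, pairwise exact-match interrater agreement (plain
percentages — no chance correction), and Spearman's rho between per-item
mean clarity and per-item mean domain fidelity (tie-corrected ranks, with
the large-sample p-value).  When either score vector is constant the rank
correlation is undefined and is reported as NaN with an explicit flag —
never silently as 0.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import VerbalizationRecord, axiom_type_of_item_id

__all__ = [
    "RatingRecord",
    "EvaluationSummary",
    "DIMENSIONS",
    "make_rating_sheet",
    "read_ratings",
    "write_ratings",
    "percent_agreement",
    "summarize",
    "summarize_by_type",
]

DIMENSIONS = ("clarity", "nl_fidelity", "domain_fidelity")

_SCALE = frozenset({1, 2, 3})
_YES_NO = frozenset({"yes", "no"})


@dataclass(frozen=True)
class RatingRecord:
    """One reviewer's three scores for one verbalized axiom."""

    item_id: str
    rater_id: str
    clarity: int
    nl_fidelity: str
    domain_fidelity: int

    def __post_init__(self) -> None:
        if self.clarity not in _SCALE:
            raise ValueError(f"clarity must be 1, 2 or 3, got {self.clarity!r}")
        if self.domain_fidelity not in _SCALE:
            raise ValueError(f"domain_fidelity must be 1, 2 or 3, got {self.domain_fidelity!r}")
        if self.nl_fidelity not in _YES_NO:
            raise ValueError(f"nl_fidelity must be 'yes' or 'no', got {self.nl_fidelity!r}")


@dataclass
class EvaluationSummary:
    """Aggregated ratings for one group of items (an ontology, or one axiom type)."""

    n_items: int
    n_raters: int
    clarity_mean: float
    clarity_sd: float
    nl_fidelity_pct_yes: float
    domain_fidelity_mean: float
    domain_fidelity_sd: float
    agreement: dict[str, float] = field(default_factory=dict)
    spearman_rho: float = math.nan
    spearman_p: float = math.nan
    spearman_defined: bool = False


def _to_frame(ratings: Iterable[RatingRecord]) -> pd.DataFrame:
    rows = list(ratings)
    if not rows:
        raise ValueError("at least one rating is required")
    return pd.DataFrame(
        {
            "item_id": [r.item_id for r in rows],
            "rater_id": [r.rater_id for r in rows],
            "clarity": [r.clarity for r in rows],
            "nl_fidelity": [r.nl_fidelity for r in rows],
            "domain_fidelity": [r.domain_fidelity for r in rows],
        }
    )


def make_rating_sheet(
    records: Sequence[VerbalizationRecord],
    path: str | Path,
    n_raters: int = 2,
) -> Path:
    """Write the shared rating sheet for a set of verbalized axioms.

    The first columns present the item id, the axiom type, the logical form
    and the English sentence; they are followed by one empty
    clarity/nl_fidelity/domain_fidelity column triple per rater.
    """
    if not records:
        raise ValueError("cannot make a rating sheet from an empty record list")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    path = Path(path)
    header = ["item_id", "axiom_type", "logic", "nl_sentence"]
    for i in range(1, n_raters + 1):
        header += [f"rater{i}_clarity", f"rater{i}_nl_fidelity", f"rater{i}_domain_fidelity"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for rec in records:
            writer.writerow(
                [rec.item_id, rec.axiom_type, rec.manchester, rec.sentence]
                + [""] * (3 * n_raters)
            )
    return path


def write_ratings(ratings: Sequence[RatingRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["item_id", "rater_id", "clarity", "nl_fidelity", "domain_fidelity"])
        for r in ratings:
            writer.writerow([r.item_id, r.rater_id, r.clarity, r.nl_fidelity, r.domain_fidelity])
    return path


def read_ratings(path: str | Path) -> list[RatingRecord]:
    """Read a long-form rating CSV; malformed rows raise with the row number."""
    out: list[RatingRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    RatingRecord(
                        item_id=row["item_id"],
                        rater_id=row["rater_id"],
                        clarity=int(row["clarity"]),
                        nl_fidelity=row["nl_fidelity"].strip().lower(),
                        domain_fidelity=int(row["domain_fidelity"]),
                    )
                )
            except (KeyError, ValueError, AttributeError) as exc:
                raise ValueError(f"{path}: malformed rating at row {lineno}: {exc}") from exc
    return out


def percent_agreement(
    r1: Sequence[RatingRecord], r2: Sequence[RatingRecord], dimension: str
) -> float:
    """Exact-match agreement between two raters on one dimension, in percent.

    Both raters must have rated exactly the same items.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    s1 = {r.item_id: getattr(r, dimension) for r in r1}
    s2 = {r.item_id: getattr(r, dimension) for r in r2}
    if set(s1) != set(s2):
        diff = sorted(set(s1) ^ set(s2))
        raise ValueError(f"raters did not rate the same items; differing ids: {diff}")
    if not s1:
        raise ValueError("cannot compute agreement over zero items")
    matches = sum(1 for item, score in s1.items() if s2[item] == score)
    return 100.0 * matches / len(s1)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan, False
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), True


def summarize(ratings: Iterable[RatingRecord]) -> EvaluationSummary:
    """Aggregate all ratings for one group of items into a summary."""
    df = _to_frame(ratings)
    per_item = df.groupby("item_id").agg(
        clarity=("clarity", "mean"),
        domain=("domain_fidelity", "mean"),
    )
    # population SD: a group whose raters all scored 1 reports (1.00, 0)
    clarity_mean = float(per_item["clarity"].mean())
    clarity_sd = float(per_item["clarity"].std(ddof=0))
    domain_mean = float(per_item["domain"].mean())
    domain_sd = float(per_item["domain"].std(ddof=0))
    pct_yes = 100.0 * float((df["nl_fidelity"] == "yes").mean())

    raters = sorted(df["rater_id"].unique())
    agreement: dict[str, float] = {}
    if len(raters) >= 2:
        by_rater = {
            rid: [
                RatingRecord(r.item_id, r.rater_id, r.clarity, r.nl_fidelity, r.domain_fidelity)
                for r in df[df["rater_id"] == rid].itertuples(index=False)
            ]
            for rid in raters
        }
        for dim in DIMENSIONS:
            vals = [
                percent_agreement(by_rater[a], by_rater[b], dim)
                for i, a in enumerate(raters)
                for b in raters[i + 1 :]
            ]
            agreement[dim] = float(np.mean(vals))

    rho, p, defined = _spearman(
        per_item["clarity"].to_numpy(float), per_item["domain"].to_numpy(float)
    )
    return EvaluationSummary(
        n_items=len(per_item),
        n_raters=len(raters),
        clarity_mean=clarity_mean,
        clarity_sd=clarity_sd,
        nl_fidelity_pct_yes=pct_yes,
        domain_fidelity_mean=domain_mean,
        domain_fidelity_sd=domain_sd,
        agreement=agreement,
        spearman_rho=rho,
        spearman_p=p,
        spearman_defined=defined,
    )


def summarize_by_type(
    ratings: Iterable[RatingRecord],
    records: Optional[Sequence[VerbalizationRecord]] = None,
) -> dict[str, EvaluationSummary]:
    """Per-axiom-type summaries; groups with no ratings are omitted.

    The axiom type of each item is taken from ``records`` when given, else
    recovered from the type-name prefix embedded in each item id.
    """
    rows = list(ratings)
    if records is not None:
        type_of = {rec.item_id: rec.axiom_type for rec in records}
    else:
        type_of = {}
    grouped: dict[str, list[RatingRecord]] = {}
    for r in rows:
        t = type_of.get(r.item_id) or axiom_type_of_item_id(r.item_id)
        grouped.setdefault(t, []).append(r)
    return {t: summarize(g) for t, g in sorted(grouped.items())}


def summary_frame(summaries: dict[str, EvaluationSummary]) -> pd.DataFrame:
    """Flatten summaries into a table mirroring the rating-report layout."""
    rows = []
    for name, s in summaries.items():
        rows.append(
            {
                "group": name,
                "n_items": s.n_items,
                "n_raters": s.n_raters,
                "clarity_mean": s.clarity_mean,
                "clarity_sd": s.clarity_sd,
                "nl_fidelity_pct_yes": s.nl_fidelity_pct_yes,
                "domain_fidelity_mean": s.domain_fidelity_mean,
                "domain_fidelity_sd": s.domain_fidelity_sd,
                "agreement_clarity": s.agreement.get("clarity"),
                "agreement_nl_fidelity": s.agreement.get("nl_fidelity"),
                "agreement_domain_fidelity": s.agreement.get("domain_fidelity"),
                "spearman_rho": s.spearman_rho if s.spearman_defined else None,
                "spearman_p": s.spearman_p if s.spearman_defined else None,
                "spearman_defined": s.spearman_defined,
            }
        )
    return pd.DataFrame(rows)
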