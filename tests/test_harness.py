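"""Rating-sheet layout, agreement, summaries and rank correlation."""

from __future__ import annotations

import csv
import math
import random

import pytest

from owlverbal import (
    RatingRecord,
    make_rating_sheet,
    percent_agreement,
    summarize,
    summarize_by_type,
)
from owlverbal.model import VerbalizationRecord

from conftest import brute_force_spearman


def _rec(i, t="SubClassOf"):
    return VerbalizationRecord(t, f"C:{i} SubClassOf: D:{i}", f"every c{i} is a d{i}")


def _rating(i, rater, clarity, nl="yes", domain=1, t="SubClassOf"):
    return RatingRecord(_rec(i, t).item_id, rater, clarity, nl, domain)


# -- rating sheet ------------------------------------------------------------


def test_sheet_layout_rows_and_columns(tmp_path):
    path = make_rating_sheet([_rec(i) for i in range(3)], tmp_path / "sheet.csv", n_raters=2)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    assert len(rows) == 4  # header + 3 items
    assert len(rows[0]) == 4 + 6  # 4 presentation columns + 3 per rater
    assert rows[0][:4] == ["item_id", "axiom_type", "logic", "nl_sentence"]


def test_sheet_contains_axiom_type_and_sentence(tmp_path, paper_axset):
    from owlverbal import verbalize_all

    records = verbalize_all(paper_axset)
    path = make_rating_sheet(records, tmp_path / "sheet.csv")
    text = path.read_text()
    assert "SubClassOf" in text
    assert "every human subject unable to give informed consent is a human subject" in text


def test_empty_record_list_is_an_error_and_writes_nothing(tmp_path):
    target = tmp_path / "sheet.csv"
    with pytest.raises(ValueError):
        make_rating_sheet([], target)
    assert not target.exists()


# -- percent agreement -------------------------------------------------------


def test_identical_raters_agree_100_percent():
    r1 = [_rating(i, "a", 1 + i % 3) for i in range(6)]
    r2 = [_rating(i, "b", 1 + i % 3) for i in range(6)]
    for dim in ("clarity", "nl_fidelity", "domain_fidelity"):
        assert percent_agreement(r1, r2, dim) == 100.0


def test_one_of_four_disagreements_gives_75_percent():
    r1 = [_rating(i, "a", 1) for i in range(4)]
    r2 = [_rating(i, "b", 1) for i in range(3)] + [_rating(3, "b", 2)]
    assert percent_agreement(r1, r2, "clarity") == 75.0


def test_mismatched_item_sets_report_symmetric_difference():
    r1 = [_rating(1, "a", 1), _rating(2, "a", 1)]
    r2 = [_rating(2, "b", 1), _rating(3, "b", 1)]
    with pytest.raises(ValueError) as err:
        percent_agreement(r1, r2, "clarity")
    msg = str(err.value)
    assert _rating(1, "a", 1).item_id in msg and _rating(3, "b", 1).item_id in msg


def test_simulated_disagreement_rate_recovered():
    # 200 items, independent disagreement with p = 0.14 per item
    rng = random.Random(5)
    r1, r2 = [], []
    expected_disagreements = 0
    for i in range(200):
        c = rng.choice([1, 2, 3])
        r1.append(_rating(i, "a", c))
        if rng.random() < 0.14:
            expected_disagreements += 1
            c = rng.choice([v for v in (1, 2, 3) if v != c])
        r2.append(_rating(i, "b", c))
    got = percent_agreement(r1, r2, "clarity")
    assert got == 100.0 * (200 - expected_disagreements) / 200
    assert abs(got - 86.0) < 3 * 100 * math.sqrt(0.14 * 0.86 / 200)


# -- summaries ---------------------------------------------------------------


def test_single_rating_degenerate_summary():
    s = summarize([_rating(0, "a", 2, "yes", 1)])
    assert s.clarity_mean == 2.0 and s.domain_fidelity_mean == 1.0
    assert s.nl_fidelity_pct_yes == 100.0
    assert not s.spearman_defined and math.isnan(s.spearman_rho)
    assert s.agreement == {}  # a single rater has no counterpart


def test_monotone_ratings_give_rho_exactly_one():
    ratings = [_rating(i, "a", 1 + i % 3, "yes", 1 + i % 3) for i in range(20)]
    s = summarize(ratings)
    assert s.spearman_defined
    assert s.spearman_rho == 1.0


def test_constant_vector_flags_rho_undefined_not_zero():
    ratings = [_rating(i, "a", 1, "yes", 1 + i % 3) for i in range(10)]
    s = summarize(ratings)
    assert not s.spearman_defined
    assert math.isnan(s.spearman_rho)


def test_spearman_matches_brute_force_oracle_with_ties():
    rng = random.Random(11)
    ratings = []
    for i in range(50):
        for rater in ("a", "b"):
            ratings.append(
                _rating(i, rater, rng.choice([1, 2, 3]), "yes", rng.choice([1, 2, 3]))
            )
    s = summarize(ratings)
    per_item_c, per_item_d = {}, {}
    for r in ratings:
        per_item_c.setdefault(r.item_id, []).append(r.clarity)
        per_item_d.setdefault(r.item_id, []).append(r.domain_fidelity)
    items = sorted(per_item_c)
    x = [sum(per_item_c[i]) / len(per_item_c[i]) for i in items]
    y = [sum(per_item_d[i]) / len(per_item_d[i]) for i in items]
    assert s.spearman_rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)


def test_rho_invariant_under_monotone_transform():
    rng = random.Random(3)
    base = [(rng.choice([1, 2, 3]), rng.choice([1, 2, 3])) for _ in range(40)]
    x = [c for c, _ in base]
    y = [d for _, d in base]
    assert brute_force_spearman(x, y) == pytest.approx(
        brute_force_spearman([10 * v**3 for v in x], y), abs=1e-12
    )


def test_summary_invariant_under_row_permutation():
    rng = random.Random(9)
    ratings = [
        _rating(i, rater, rng.choice([1, 2, 3]), rng.choice(["yes", "no"]), rng.choice([1, 2, 3]))
        for i in range(30)
        for rater in ("a", "b")
    ]
    shuffled = ratings[:]
    rng.shuffle(shuffled)
    assert summarize(ratings) == summarize(shuffled)


# -- per-type summaries ------------------------------------------------------


def test_two_type_fixture_gives_two_groups():
    ratings = [_rating(i, "a", 1, t="SubClassOf") for i in range(3)]
    ratings += [_rating(i, "a", 2, t="DisjointClasses") for i in range(10, 12)]
    groups = summarize_by_type(ratings)
    assert set(groups) == {"SubClassOf", "DisjointClasses"}
    assert groups["SubClassOf"].n_items == 3
    assert groups["DisjointClasses"].n_items == 2


def test_single_type_totals_conserved():
    ratings = [_rating(i, "a", 1 + i % 3) for i in range(9)]
    groups = summarize_by_type(ratings)
    assert list(groups) == ["SubClassOf"]
    assert groups["SubClassOf"].n_items == 9


def test_group_means_recombine_to_pooled_mean():
    rng = random.Random(21)
    ratings = []
    for t, n in (("SubClassOf", 12), ("ClassAssertion", 7), ("DisjointClasses", 5)):
        for i in range(n):
            ratings.append(_rating(f"{t}{i}", "a", rng.choice([1, 2, 3]), t=t))
    pooled = summarize(ratings)
    groups = summarize_by_type(ratings)
    total = sum(s.n_items for s in groups.values())
    weighted = sum(s.clarity_mean * s.n_items for s in groups.values()) / total
    assert pooled.n_items == total
    assert pooled.clarity_mean == pytest.approx(weighted, abs=1e-12)
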