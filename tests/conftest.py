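"""Shared fixtures: ontology files are generated fresh into a session tmp dir."""

from __future__ import annotations

import warnings

import pytest

from owlverbal import fixtures, load_ontology, verbalize_all

warnings.filterwarnings("ignore", message="Assertions on .*")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("ontologies")


@pytest.fixture(scope="session")
def paper_ttl(fixture_dir):
    return fixtures.build_paper_examples(fixture_dir, "turtle")


@pytest.fixture(scope="session")
def paper_owl(fixture_dir):
    return fixtures.build_paper_examples(fixture_dir, "rdfxml")


@pytest.fixture(scope="session")
def people_ttl(fixture_dir):
    return fixtures.build_people_fixture(fixture_dir, "turtle")


@pytest.fixture(scope="session")
def people_owl(fixture_dir):
    return fixtures.build_people_fixture(fixture_dir, "rdfxml")


@pytest.fixture(scope="session")
def paper_axset(paper_ttl):
    return load_ontology(paper_ttl)


@pytest.fixture(scope="session")
def people_axset(people_ttl):
    return load_ontology(people_ttl)


@pytest.fixture(scope="session")
def people_records(people_axset):
    return verbalize_all(people_axset)


def brute_force_spearman(x, y) -> float:
    """Independent rank-correlation oracle: average ranks by sorting, then a
    plain-sum Pearson correlation of the ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5
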