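"""Slim mapping, category comparison, component partitioning and GAQ scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gvprotcomm.gomodel import (
    GaqConfig,
    compare_categories,
    default_evidence_weights,
    gaq_score,
    map_to_slim,
    partition_by_component,
)
from gvprotcomm.ontology import AnnotationSet, OntologyGraph


def chain_ontology() -> OntologyGraph:
    """root <- mid <- leaf (biological_process)."""
    g = OntologyGraph()
    g.add_term("root", namespace="biological_process")
    g.add_term("mid", namespace="biological_process")
    g.add_term("leaf", namespace="biological_process")
    g.add_edge("mid", "root", "is_a")
    g.add_edge("leaf", "mid", "part_of")
    return g


def annots(mapping: dict[str, set[tuple[str, str]]]) -> AnnotationSet:
    return AnnotationSet(annotations=mapping)


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyGraph:
    """Random rooted DAG: each term links to 1-2 lower-index terms."""
    g = OntologyGraph()
    for i in range(n_terms):
        g.add_term(f"T{i}", namespace="biological_process")
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3)
        for p in rng.choice(i, size=min(n_parents, i), replace=False):
            g.add_edge(f"T{i}", f"T{int(p)}", "is_a" if rng.random() < 0.7 else "part_of")
    return g


# ---------------------------------------------------------------------------
# slim mapping
# ---------------------------------------------------------------------------

def test_annotation_to_slim_term_maps_to_itself():
    g = chain_ontology()
    mapping, _ = map_to_slim(annots({"P1": {("mid", "IDA")}}), g, ["mid"])
    assert mapping == {"P1": {"mid"}}


def test_leaf_annotation_rolls_up_to_slim_ancestor():
    g = chain_ontology()
    mapping, _ = map_to_slim(annots({"P1": {("leaf", "IEA")}}), g, ["mid"])
    assert mapping == {"P1": {"mid"}}


def test_unannotated_protein_is_unclassified():
    g = chain_ontology()
    mapping, unclassified = map_to_slim(
        annots({"P1": {("root", "IEA")}}), g, ["mid"]
    )
    assert mapping == {}
    assert unclassified == {"P1"}


def test_slim_term_absent_from_ontology_errors():
    with pytest.raises(KeyError, match="absent"):
        map_to_slim(annots({}), chain_ontology(), ["nope"])


def test_slim_mapping_matches_bruteforce_on_random_ontologies():
    rng = np.random.default_rng(11)
    for _ in range(15):
        n_terms = int(rng.integers(5, 100))
        g = random_dag(rng, n_terms)
        terms = g.terms
        slim = list(rng.choice(terms, size=max(1, n_terms // 4), replace=False))
        annotations = {
            f"P{j}": {
                (str(t), "IEA") for t in rng.choice(terms, size=int(rng.integers(1, 4)))
            }
            for j in range(20)
        }
        mapping, unclassified = map_to_slim(annots(annotations), g, slim)
        # oracle: exhaustive upward closure by naive edge walking
        parent_of = {t: g.parents(t) for t in terms}
        slim_set = set(slim)
        for protein, pairs in annotations.items():
            expected = set()
            for term, _ in pairs:
                seen, frontier = {term}, set(parent_of[term])
                while frontier:
                    seen |= frontier
                    frontier = {p for t in frontier for p in parent_of[t]} - seen
                expected |= seen & slim_set
            if expected:
                assert mapping[protein] == expected
            else:
                assert protein in unclassified


def test_enlarging_slim_never_shrinks_category_count():
    rng = np.random.default_rng(4)
    g = random_dag(rng, 40)
    annotations = annots(
        {f"P{j}": {(f"T{int(rng.integers(40))}", "IEA")} for j in range(15)}
    )
    small = [f"T{i}" for i in range(0, 40, 8)]
    large = small + [f"T{i}" for i in range(1, 40, 8)]
    map_small, _ = map_to_slim(annotations, g, small)
    map_large, _ = map_to_slim(annotations, g, large)
    for protein, cats in map_small.items():
        assert cats <= map_large[protein]


# ---------------------------------------------------------------------------
# category comparison
# ---------------------------------------------------------------------------

def test_identical_percentages_give_p_one():
    slim_map = {f"P{i}": {"cat"} for i in range(5)}
    slim_map.update({f"Q{i}": set() for i in range(5)})
    universe = set(slim_map)
    annotated = {p for p, c in slim_map.items() if c} | set(slim_map)
    presence = {(s, r): set(universe) for s in ("oocyte", "cumulus") for r in (1, 2, 3)}
    out = compare_categories(slim_map, presence, ("oocyte", "cumulus"))
    row = out[out["category"] == "cat"].iloc[0]
    assert row["pvalue"] == 1.0 and not row["significant"]


def test_pooled_t_hand_computed():
    # per-replicate percentages {10,12,14} vs {20,22,24}: pooled SD 2, t = -6.12 on 4 df
    slim_map = {f"P{i}": {"cat"} for i in range(30)}
    slim_map.update({f"Q{i}": {"other"} for i in range(100)})
    p_members = [f"P{i}" for i in range(30)]
    q_members = [f"Q{i}" for i in range(100)]

    # construct replicates whose "cat" percentage is exactly the target
    def rep_exact(pct: int) -> set:
        n_cat = pct  # out of 100 proteins total
        return set(p_members[:n_cat]) | set(q_members[: 100 - n_cat])

    presence = {
        ("oocyte", 1): rep_exact(10),
        ("oocyte", 2): rep_exact(12),
        ("oocyte", 3): rep_exact(14),
        ("cumulus", 1): rep_exact(20),
        ("cumulus", 2): rep_exact(22),
        ("cumulus", 3): rep_exact(24),
    }
    out = compare_categories(slim_map, presence, ("oocyte", "cumulus"))
    row = out[out["category"] == "cat"].iloc[0]
    assert row["pct_oocyte"] == pytest.approx(12.0)
    assert row["pct_cumulus"] == pytest.approx(22.0)
    assert row["t"] == pytest.approx(-6.1237, abs=1e-3)
    assert row["pvalue"] == pytest.approx(float(2 * sps.t.sf(6.1237, 4)), abs=1e-4)
    assert row["significant"]


def test_category_counts_match_recount(small_bundle, small_sim):
    from gvprotcomm.io import read_gaf, read_obo

    _, truth = small_sim
    # materialise the bundle through the readers so the whole path is exercised
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        paths = small_bundle.write(d)
        ontology = read_obo(paths["obo"])
        annotations = read_gaf(paths["gaf"])
    bp = annotations.by_namespace(ontology, "biological_process")
    mapping, _ = map_to_slim(bp, ontology, small_bundle.slim_terms)
    accs = list(truth.frame["accession"])
    presence = {("oocyte", 1): set(accs[:30]), ("oocyte", 2): set(accs[:30]),
                ("cumulus", 1): set(accs[30:]), ("cumulus", 2): set(accs[30:])}
    out = compare_categories(mapping, presence, ("oocyte", "cumulus"))
    for _, row in out.iterrows():
        cat = row["category"]
        expected_oo = {p for p in set(accs[:30]) & set(mapping) if cat in mapping[p]}
        assert row["n_oocyte"] == len(expected_oo)


# ---------------------------------------------------------------------------
# component partition
# ---------------------------------------------------------------------------

def cc_ontology() -> OntologyGraph:
    g = OntologyGraph()
    g.add_term("cc_root", namespace="cellular_component")
    for t in ("membrane", "nucleus"):
        g.add_term(t, namespace="cellular_component")
        g.add_edge(t, "cc_root", "is_a")
    g.add_term("plasma_membrane", namespace="cellular_component")
    g.add_edge("plasma_membrane", "membrane", "is_a")
    return g


def build_partition_inputs(n_cc_only: int, n_oo_only: int, n_both: int, term: str):
    proteins = [f"X{i}" for i in range(n_cc_only + n_oo_only + n_both)]
    membership = pd.Series(
        ["cumulus-only"] * n_cc_only + ["oocyte-only"] * n_oo_only + ["common"] * n_both,
        index=proteins,
    )
    # annotate half directly, half via a descendant
    ann = {}
    for i, p in enumerate(proteins):
        chosen = term if i % 2 == 0 and term == "membrane" else (
            "plasma_membrane" if term == "membrane" else term)
        ann[p] = {(chosen, "IDA")}
    return annots(ann), membership


@pytest.mark.parametrize(
    "n_cc, n_oo, n_both, total",
    [(248, 84, 72, 404), (172, 46, 55, 273)],  # membrane-like and nucleus-like splits
)
def test_component_partition_set_arithmetic(n_cc, n_oo, n_both, total):
    g = cc_ontology()
    term = "membrane" if total == 404 else "nucleus"
    annotations, membership = build_partition_inputs(n_cc, n_oo, n_both, term)
    counts = partition_by_component(annotations, membership, term, g)
    assert counts["cumulus-only"] == n_cc
    assert counts["oocyte-only"] == n_oo
    assert counts["common"] == n_both
    assert counts["total"] == total


def test_empty_annotations_give_zero_partition():
    g = cc_ontology()
    membership = pd.Series(["common"], index=["P1"])
    counts = partition_by_component(annots({}), membership, "membrane", g)
    assert counts["total"] == 0


def test_component_term_must_be_cellular_component():
    g = cc_ontology()
    g.add_term("bp_term", namespace="biological_process")
    with pytest.raises(ValueError):
        partition_by_component(annots({}), pd.Series(dtype=object), "bp_term", g)
    with pytest.raises(KeyError):
        partition_by_component(annots({}), pd.Series(dtype=object), "missing", g)


# ---------------------------------------------------------------------------
# GAQ
# ---------------------------------------------------------------------------

def test_gaq_zero_without_annotations():
    g = chain_ontology()
    scores, mean = gaq_score(annots({}), g, proteins=["P1"])
    assert scores["P1"] == 0 and mean == 0.0


def test_gaq_single_annotation_product():
    g = chain_ontology()
    config = GaqConfig(weights={"IDA": 4})
    # depth(leaf) = 2 in the chain; use weight 4 -> custom chain of depth 3
    g.add_term("subleaf", namespace="biological_process")
    g.add_edge("subleaf", "leaf", "is_a")
    scores, _ = gaq_score(annots({"P1": {("subleaf", "IDA")}}), g, config)
    assert scores["P1"] == 3 * 4


def test_gaq_additive_and_order_invariant():
    g = chain_ontology()
    config = GaqConfig(weights={"IDA": 4, "IEA": 1})
    a1 = annots({"P1": {("mid", "IDA"), ("leaf", "IEA")}})
    a2 = annots({"P1": {("leaf", "IEA"), ("mid", "IDA")}})
    s1, _ = gaq_score(a1, g, config)
    s2, _ = gaq_score(a2, g, config)
    assert s1["P1"] == s2["P1"] == 1 * 4 + 2 * 1
    # adding an annotation never decreases the score
    s3, _ = gaq_score(annots({"P1": {("mid", "IDA"), ("leaf", "IEA"), ("root", "IDA")}}), g, config)
    assert s3["P1"] >= s1["P1"]


def test_gaq_matches_bruteforce_bfs_depth_oracle():
    rng = np.random.default_rng(23)
    weights = default_evidence_weights()
    codes = list(weights)
    for _ in range(10):
        g = random_dag(rng, int(rng.integers(5, 100)))
        terms = g.terms
        annotations = {
            f"P{j}": {
                (str(t), codes[int(rng.integers(len(codes)))])
                for t in rng.choice(terms, size=int(rng.integers(1, 5)))
            }
            for j in range(10)
        }
        scores, mean = gaq_score(annots(annotations), g)
        # oracle: BFS depth to T0 over child->parent adjacency
        parent_of = {t: g.parents(t) for t in terms}

        def bfs_depth(term: str) -> int:
            level, frontier = 0, {term}
            while "T0" not in frontier:
                frontier = {p for t in frontier for p in parent_of[t]}
                level += 1
            return level

        for protein, pairs in annotations.items():
            expected = sum(bfs_depth(t) * weights[e] for t, e in pairs)
            assert scores[protein] == expected
        assert mean == pytest.approx(np.mean(list(scores)))


def test_mean_gaq_increases_when_iea_upgraded_to_experimental():
    g = chain_ontology()
    before = annots({f"P{i}": {("leaf", "IEA")} for i in range(10)})
    after = annots({f"P{i}": {("leaf", "IDA")} for i in range(10)})
    _, mean_before = gaq_score(before, g)
    _, mean_after = gaq_score(after, g)
    assert mean_after > mean_before


def test_unknown_evidence_code_errors_without_default():
    g = chain_ontology()
    with pytest.raises(KeyError):
        gaq_score(annots({"P1": {("mid", "XXX")}}), g)
    scores, _ = gaq_score(annots({"P1": {("mid", "XXX")}}), g,
                          GaqConfig(default_weight=2))
    assert scores["P1"] == 1 * 2
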