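"""GO-slim functional profiling and GAQ annotation-quality scoring.

Profiling maps each protein's annotations up the ontology into a reduced set
of mid-level "slim" categories and compares category percentages between cell
types by Student's t-test on per-replicate values.  The GAQ (GO Annotation
Quality) score summarises, per protein, how many annotations it has, how
specific they are (term depth) and how strong their evidence codes are:

    GAQ(protein) = sum over annotations of depth(term) * weight(evidence)

Depth is the shortest is_a/part_of path to the namespace root.  Evidence-code
weights ship as a data table (experimental codes weigh most, IEA least) and
are fully configurable.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gvprotcomm.ontology import AnnotationSet, OntologyGraph


def default_evidence_weights() -> dict[str, int]:
    """Evidence-code weight table shipped with the package."""
    path = resources.files("gvprotcomm").joinpath("data/ec_weights.tsv")
    with resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t")
    return dict(zip(table["evidence_code"], table["weight"].astype(int)))


@dataclasses.dataclass
class GaqConfig:
    """Weights per evidence code; ``default_weight`` (if set) covers unknown codes."""

    weights: Mapping[str, int] = dataclasses.field(default_factory=default_evidence_weights)
    default_weight: int | None = None

    def weight(self, evidence: str) -> int:
        if evidence in self.weights:
            w = int(self.weights[evidence])
        elif self.default_weight is not None:
            w = int(self.default_weight)
        else:
            raise KeyError(f"unknown evidence code {evidence!r} and no default weight")
        if w < 0:
            raise ValueError(f"negative weight for evidence code {evidence!r}")
        return w


# ---------------------------------------------------------------------------
# slim mapping
# ---------------------------------------------------------------------------

def map_to_slim(
    annotations: AnnotationSet,
    ontology: OntologyGraph,
    slim: Sequence[str],
) -> tuple[dict[str, set[str]], set[str]]:
    """Map each protein to the slim categories covering its annotations.

    A protein maps to slim term ``s`` iff some annotated term equals ``s`` or
    has ``s`` among its is_a/part_of ancestors.  Returns the mapping and the
    set of proteins covered by no slim term ("unclassified").
    """
    slim_set = set(slim)
    missing = slim_set - {t for t in slim_set if t in ontology}
    if missing:
        raise KeyError(f"slim terms absent from ontology: {sorted(missing)}")
    # one upward closure per distinct annotated term
    closure: dict[str, set[str]] = {}
    mapping: dict[str, set[str]] = {}
    unclassified: set[str] = set()
    for protein in annotations.proteins():
        cats: set[str] = set()
        for term in annotations.terms_for(protein):
            if term not in ontology:
                continue
            if term not in closure:
                closure[term] = ({term} | ontology.ancestors(term)) & slim_set
            cats |= closure[term]
        if cats:
            mapping[protein] = cats
        else:
            unclassified.add(protein)
    return mapping, unclassified


def compare_categories(
    slim_map: Mapping[str, set[str]],
    presence: Mapping[tuple[str, int], set[str]],
    samples: tuple[str, str],
    categories: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category percentages per replicate and a between-cell-type t-test.

    ``presence[(sample, replicate)]`` is the set of proteins observed in that
    replicate.  The percentage unit is: proteins of the category present in
    the replicate, divided by slim-annotated proteins present in the
    replicate, x100 — so the t-test has per-replicate replication.  Pooled
    (Student's) two-sided t; zero pooled variance with equal means gives
    p = 1.
    """
    if categories is None:
        categories = sorted({c for cats in slim_map.values() for c in cats})
    reps: dict[str, list[int]] = {s: [] for s in samples}
    for s, r in presence:
        if s in reps:
            reps[s].append(r)
    for s in samples:
        if len(reps[s]) < 2:
            raise ValueError(f"cell type {s!r} needs >=2 replicates, has {len(reps[s])}")
    annotated = set(slim_map)
    pct: dict[str, dict[str, list[float]]] = {c: {s: [] for s in samples} for c in categories}
    counts = {c: {s: set() for s in samples} for c in categories}
    for (s, r), proteins in presence.items():
        if s not in reps:
            continue
        denom = len(proteins & annotated)
        for c in categories:
            members = {p for p in proteins & annotated if c in slim_map[p]}
            pct[c][s].append(100.0 * len(members) / denom if denom else 0.0)
            counts[c][s] |= members

    rows = []
    a_name, b_name = samples
    for c in categories:
        a = np.asarray(pct[c][a_name])
        b = np.asarray(pct[c][b_name])
        t, p = _pooled_t(a, b)
        rows.append(
            {
                "category": c,
                f"n_{a_name}": len(counts[c][a_name]),
                f"n_{b_name}": len(counts[c][b_name]),
                f"pct_{a_name}": float(a.mean()),
                f"pct_{b_name}": float(b.mean()),
                "t": t,
                "pvalue": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    df = len(a) + len(b) - 2
    pooled_var = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if pooled_var <= 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    se = np.sqrt(pooled_var * (1 / len(a) + 1 / len(b)))
    t = float((a.mean() - b.mean()) / se)
    return t, float(2.0 * stats.t.sf(abs(t), df))


# ---------------------------------------------------------------------------
# cellular-component partitioning
# ---------------------------------------------------------------------------

def partition_by_component(
    annotations: AnnotationSet,
    membership: pd.Series,
    component_term: str,
    ontology: OntologyGraph,
) -> dict[str, int]:
    """Count proteins of a cellular component, split by cell-type membership.

    A protein counts iff annotated to ``component_term`` or any of its
    descendants.  Returns counts per membership class plus their total.
    """
    if component_term not in ontology:
        raise KeyError(f"component term not found: {component_term}")
    if ontology.namespace(component_term) != "cellular_component":
        raise ValueError(f"{component_term} is not a cellular_component term")
    relevant = {component_term} | ontology.descendants(component_term)
    in_component = {
        p for p in annotations.proteins() if annotations.terms_for(p) & relevant
    }
    classes = [c for c in membership.unique() if c != "absent"]
    counts = {
        cls: int(sum(1 for p in in_component if p in membership.index and membership[p] == cls))
        for cls in sorted(classes)
    }
    counts["total"] = sum(counts.values())
    return counts


# ---------------------------------------------------------------------------
# GAQ scoring
# ---------------------------------------------------------------------------

def gaq_score(
    annotations: AnnotationSet,
    ontology: OntologyGraph,
    config: GaqConfig | None = None,
    proteins: Sequence[str] | None = None,
) -> tuple[pd.Series, float]:
    """Per-protein GAQ scores and the dataset mean.

    ``proteins`` fixes the scoring universe (unannotated members score 0);
    by default the annotated proteins are scored.  The score is additive over
    annotations, so adding an annotation never decreases it.
    """
    config = config or GaqConfig()
    universe = list(proteins) if proteins is not None else sorted(annotations.proteins())
    depth_cache: dict[str, int] = {}
    scores = {}
    for protein in universe:
        total = 0
        for term, evidence in annotations.pairs_for(protein):
            if term not in ontology:
                raise KeyError(f"annotation term absent from ontology: {term}")
            if term not in depth_cache:
                depth_cache[term] = ontology.depth(term)
            total += depth_cache[term] * config.weight(evidence)
        scores[protein] = total
    series = pd.Series(scores, name="gaq", dtype=float)
    mean = float(series.mean()) if len(series) else 0.0
    return series, mean
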