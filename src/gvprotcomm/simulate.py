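"""Ground-truthed synthetic inputs for the whole pipeline.

Emulates a two-cell-type shotgun proteomics design: two cell types (oocyte,
cumulus) x replicates x differential-detergent fractions of target and decoy
PSMs, with per-charge Xcorr distributions that differ between correct and
random matches, a configurable fraction of truly differential proteins, and a
matching toy annotation bundle (OBO ontology, GAF annotations, slim list, GMT
gene sets, agonist/antagonist regulation table).

Statistical choices: PSM counts per protein per replicate are negative
binomial (Poisson in the large-dispersion limit) with mean proportional to
true abundance; Xcorr is per-charge Gaussian truncated at zero for both
populations; peptide sequences are deterministic pseudo-tryptic strings keyed
by protein index, with no amino-acid chemistry simulated.  Fixing the seed
makes every emitted file byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from gvprotcomm.io import (
    DECOY_PREFIX,
    write_gaf,
    write_gmt,
    write_psm_table,
    write_regulation,
)

OOCYTE = "oocyte"
CUMULUS = "cumulus"

_RESIDUES = np.array(list("ACDEFGHIKLMNPQSTVWY"))

# fixed toy ontology layout: (term id, name, namespace, [(parent, rel), ...])
_BP_ROOT = "GO:1000000"
_CC_ROOT = "GO:2000000"
_SLIM_NAMES = [
    "signal transduction",
    "cell cycle regulation",
    "DNA transcription",
    "apoptosis regulation",
    "protein metabolism and modification",
    "generation of precursor metabolites and energy",
    "cytoskeleton organization and biogenesis",
    "response to stress",
    "transport",
    "cell communication",
]


@dataclasses.dataclass
class SimulationConfig:
    """Stated world for the synthetic experiment.

    Defaults mirror the emulated design: two cell types, three replicates,
    four fractions, ~20 PSMs per protein at baseline abundance, a 1:1
    decoy-to-target match ratio, and clearly separated correct vs random
    Xcorr distributions per charge.
    """

    n_proteins: int = 200
    frac_shared: float = 0.2
    frac_differential: float = 0.3
    fold_effect: float = 3.0
    frac_up: float = 0.8  # share of differential proteins higher in cumulus
    n_replicates: int = 3
    n_fractions: int = 4
    mean_psms_per_protein: float = 20.0
    dispersion: float = 50.0  # negative-binomial size; Poisson as -> inf
    # size 50 ~ CV 0.14 beyond Poisson: technical-replicate-level reproducibility,
    # matching a design whose replicates are pooled samples of hundreds of cells
    charge_probs: tuple[float, float, float] = (0.2, 0.5, 0.3)
    xcorr_correct_params: Mapping[int, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {1: (2.8, 0.5), 2: (3.3, 0.6), 3: (4.6, 0.7)}
    )
    xcorr_random_params: Mapping[int, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {1: (1.0, 0.4), 2: (1.2, 0.45), 3: (1.5, 0.5)}
    )
    deltacn_correct: tuple[float, float] = (0.28, 0.08)
    deltacn_random: tuple[float, float] = (0.08, 0.05)
    decoy_ratio: float = 1.0
    # annotation-bundle knobs
    min_annotations: int = 1
    max_annotations: int = 3
    cc_annotation_prob: float = 0.4
    evidence_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"IEA": 0.6, "ISS": 0.2, "IDA": 0.15, "TAS": 0.05}
    )
    n_gene_sets: int = 12
    geneset_size_range: tuple[int, int] = (8, 25)
    regulation_frac: float = 0.3
    agonist_prob: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        for name in ("frac_shared", "frac_differential", "frac_up",
                     "cc_annotation_prob", "regulation_frac", "agonist_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not np.isclose(sum(self.charge_probs), 1.0):
            raise ValueError("charge_probs must sum to 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_fractions < 1 or self.mean_psms_per_protein <= 0:
            raise ValueError("n_fractions and mean_psms_per_protein must be positive")
        if self.fold_effect <= 0 or self.decoy_ratio < 0 or self.dispersion <= 0:
            raise ValueError("fold_effect/dispersion must be positive, decoy_ratio >= 0")
        ev_total = sum(self.evidence_probs.values())
        if not np.isclose(ev_total, 1.0):
            raise ValueError("evidence_probs must sum to 1")


@dataclasses.dataclass
class GroundTruth:
    """Per-protein truth: membership, abundances, differential flag/direction."""

    frame: pd.DataFrame  # accession, membership, abundance_oocyte, abundance_cumulus,
    #                      differential, direction

    def __post_init__(self) -> None:
        diff = self.frame[self.frame["differential"]]
        if not (diff["membership"] == "common").all():
            raise ValueError("differential proteins must be common to both cell types")

    @property
    def membership_counts(self) -> dict[str, int]:
        return self.frame["membership"].value_counts().to_dict()

    @property
    def differential_accessions(self) -> set[str]:
        return set(self.frame.loc[self.frame["differential"], "accession"])

    def direction_of(self, accession: str) -> str:
        row = self.frame.set_index("accession").loc[accession]
        return row["direction"]

    def write(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["differential"] = out["differential"].map({True: "true", False: "false"})
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
        frame["differential"] = frame["differential"] == "true"
        return cls(frame=frame)


def _peptide_pool(key: int, n_peptides: int = 8) -> list[str]:
    """Deterministic pseudo-tryptic peptides keyed by protein index."""
    rng = np.random.default_rng(900_000_000 + key)
    peptides = []
    for _ in range(n_peptides):
        length = int(rng.integers(7, 15))
        body = "".join(rng.choice(_RESIDUES, size=length - 1))
        peptides.append(body + ("K" if rng.random() < 0.5 else "R"))
    return peptides


def _truncnorm(rng: np.random.Generator, loc, scale, size, low=0.0, high=np.inf):
    a = (low - np.asarray(loc)) / scale
    b = (high - np.asarray(loc)) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _negbin(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    p = size_param / (size_param + mean[pos])
    out[pos] = rng.negative_binomial(size_param, p)
    return out


def _assign_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    n = config.n_proteins
    accessions = [f"P{i:04d}" for i in range(n)]
    n_common = int(round(config.frac_shared * n))
    n_rest = n - n_common
    n_oo = n_rest // 2
    membership = (
        ["common"] * n_common + ["oocyte-only"] * n_oo + ["cumulus-only"] * (n_rest - n_oo)
    )
    n_diff = int(round(config.frac_differential * n_common))
    diff_idx = rng.choice(n_common, size=n_diff, replace=False) if n_diff else np.array([], int)
    differential = np.zeros(n, dtype=bool)
    differential[diff_idx] = True
    up = rng.random(n) < config.frac_up

    ab_oo = np.zeros(n)
    ab_cc = np.zeros(n)
    direction = np.full(n, "", dtype=object)
    for i, mem in enumerate(membership):
        if mem in ("common", "oocyte-only"):
            ab_oo[i] = 1.0
        if mem in ("common", "cumulus-only"):
            ab_cc[i] = 1.0
        if differential[i]:
            if up[i]:
                ab_cc[i] *= config.fold_effect
                direction[i] = "higher"
            else:
                ab_cc[i] /= config.fold_effect
                direction[i] = "lower"
    frame = pd.DataFrame(
        {
            "accession": accessions,
            "membership": membership,
            "abundance_oocyte": ab_oo,
            "abundance_cumulus": ab_cc,
            "differential": differential,
            "direction": direction,
        }
    )
    return GroundTruth(frame=frame)


def _sample_psm_block(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample: str,
    accession_idx: np.ndarray,
    replicate: np.ndarray,
    correct: bool,
) -> pd.DataFrame:
    """Draw per-PSM attributes for one block of matches (vectorised)."""
    n = len(accession_idx)
    charge = rng.choice([1, 2, 3], size=n, p=list(config.charge_probs))
    params = config.xcorr_correct_params if correct else config.xcorr_random_params
    locs = np.array([params[z][0] for z in charge])
    scales = np.array([params[z][1] for z in charge])
    xcorr = _truncnorm(rng, locs, scales, n) if n else np.array([])
    dc_loc, dc_scale = config.deltacn_correct if correct else config.deltacn_random
    deltacn = _truncnorm(rng, dc_loc, dc_scale, n, low=0.0, high=1.0) if n else np.array([])
    if correct:
        rsp = rng.choice(
            np.arange(1, 9), size=n, p=[0.60, 0.15, 0.08, 0.07, 0.03, 0.03, 0.02, 0.02]
        )
    else:
        rsp = rng.integers(1, 11, size=n)
    fraction = rng.integers(1, config.n_fractions + 1, size=n)
    prefix = "" if correct else DECOY_PREFIX
    pools = {}
    peptides = []
    accs = []
    pep_choice = rng.integers(0, 8, size=n)
    for idx, j in zip(accession_idx, pep_choice):
        key = int(idx) if correct else 500_000 + int(idx)
        if key not in pools:
            pools[key] = _peptide_pool(key)
        peptides.append(pools[key][j])
        accs.append(f"{prefix}P{int(idx):04d}")
    return pd.DataFrame(
        {
            "sample": sample,
            "replicate": replicate,
            "fraction": fraction,
            "peptide": peptides,
            "charge": charge,
            "xcorr": np.round(xcorr, 4),
            "deltacn": np.round(deltacn, 4),
            "rsp": rsp,
            "accession": accs,
            "is_decoy": not correct,
        }
    )


def simulate_psm_tables(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate one PSM table per cell type plus the ground truth.

    Target PSM counts per (protein, replicate) are negative binomial with
    mean ``mean_psms_per_protein x true abundance``; decoy record counts are
    Poisson with mean ``decoy_ratio x target count``.  Correct and random
    matches draw Xcorr from their respective per-charge truncated normals.
    """
    rng = np.random.default_rng(config.seed)
    truth = _assign_truth(config, rng)
    abundance = {
        OOCYTE: truth.frame["abundance_oocyte"].to_numpy(),
        CUMULUS: truth.frame["abundance_cumulus"].to_numpy(),
    }
    tables: dict[str, pd.DataFrame] = {}
    for sample in (OOCYTE, CUMULUS):
        blocks = []
        n_target_total = 0
        for rep in range(1, config.n_replicates + 1):
            counts = _negbin(rng, config.mean_psms_per_protein * abundance[sample],
                             config.dispersion)
            acc_idx = np.repeat(np.arange(config.n_proteins), counts)
            n_target_total += len(acc_idx)
            blocks.append(
                _sample_psm_block(
                    config, rng, sample, acc_idx,
                    np.full(len(acc_idx), rep), correct=True,
                )
            )
        n_decoy = int(rng.poisson(config.decoy_ratio * n_target_total))
        decoy_idx = rng.integers(0, config.n_proteins, size=n_decoy)
        decoy_rep = rng.integers(1, config.n_replicates + 1, size=n_decoy)
        blocks.append(
            _sample_psm_block(config, rng, sample, decoy_idx, decoy_rep, correct=False)
        )
        table = pd.concat(blocks, ignore_index=True)
        tables[sample] = table.astype(
            {"replicate": "int64", "fraction": "int64", "charge": "int64",
             "rsp": "int64", "is_decoy": "bool"}
        )
    return tables, truth


# ---------------------------------------------------------------------------
# annotation bundle
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticBundle:
    """In-memory annotation bundle plus deterministic writers.

    ``ancestors`` records, for every term, its full is_a/part_of ancestor set
    as computed by the generator's own iterative edge walk — kept so readers
    and graph implementations can be checked against it.
    """

    terms: dict[str, tuple[str, str, bool]]  # id -> (name, namespace, obsolete)
    edges: list[tuple[str, str, str]]  # child, parent, rel
    ancestors: dict[str, set[str]]
    slim_terms: list[str]
    gaf_rows: list[tuple]
    gene_sets: dict[str, set[str]]
    regulation: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "obo": outdir / "ontology.obo",
            "gaf": outdir / "annotations.gaf",
            "slim": outdir / "slim_terms.txt",
            "gmt": outdir / "gene_sets.gmt",
            "regulation": outdir / "regulation.tsv",
        }
        with open(paths["obo"], "w") as fh:
            fh.write("format-version: 1.2\nontology: gvc-toy\n")
            for term_id in sorted(self.terms):
                name, namespace, obsolete = self.terms[term_id]
                fh.write(f"\n[Term]\nid: {term_id}\nname: {name}\nnamespace: {namespace}\n")
                for child, parent, rel in self.edges:
                    if child != term_id:
                        continue
                    if rel == "is_a":
                        fh.write(f"is_a: {parent} ! {self.terms[parent][0]}\n")
                    else:
                        fh.write(f"relationship: part_of {parent} ! {self.terms[parent][0]}\n")
                if obsolete:
                    fh.write("is_obsolete: true\n")
        write_gaf(self.gaf_rows, paths["gaf"])
        with open(paths["slim"], "w") as fh:
            fh.writelines(t + "\n" for t in self.slim_terms)
        write_gmt(self.gene_sets, paths["gmt"])
        write_regulation(self.regulation, paths["regulation"])
        return paths


def _toy_ontology() -> tuple[dict, list]:
    terms: dict[str, tuple[str, str, bool]] = {
        _BP_ROOT: ("biological_process", "biological_process", False),
        _CC_ROOT: ("cellular_component", "cellular_component", False),
        "GO:1999999": ("obsolete process", "biological_process", True),
    }
    edges: list[tuple[str, str, str]] = []
    for i, name in enumerate(_SLIM_NAMES, start=1):
        slim_id = f"GO:10000{i:02d}"
        terms[slim_id] = (name, "biological_process", False)
        edges.append((slim_id, _BP_ROOT, "is_a"))
        for j in (1, 2):
            leaf = f"GO:101{i:02d}{j}"
            terms[leaf] = (f"{name} subprocess {j}", "biological_process", False)
            edges.append((leaf, slim_id, "is_a" if j == 1 else "part_of"))
        deep = f"GO:102{i:02d}1"
        terms[deep] = (f"{name} subsubprocess", "biological_process", False)
        edges.append((deep, f"GO:101{i:02d}1", "is_a"))
    cc = {
        "GO:2000001": ("membrane", [( _CC_ROOT, "is_a")]),
        "GO:2000002": ("nucleus", [(_CC_ROOT, "is_a")]),
        "GO:2000003": ("cytoplasm", [(_CC_ROOT, "is_a")]),
        "GO:2000011": ("plasma membrane", [("GO:2000001", "is_a")]),
        "GO:2000012": ("nuclear envelope", [("GO:2000002", "part_of")]),
        "GO:2000013": ("mitochondrion", [("GO:2000003", "part_of")]),
    }
    for term_id, (name, parents) in cc.items():
        terms[term_id] = (name, "cellular_component", False)
        for parent, rel in parents:
            edges.append((term_id, parent, rel))
    return terms, edges


def _walk_ancestors(edges: list[tuple[str, str, str]]) -> dict[str, set[str]]:
    """Transitive closure by naive repeated parent expansion."""
    parents: dict[str, set[str]] = {}
    for child, parent, _ in edges:
        parents.setdefault(child, set()).add(parent)
    all_terms = set(parents) | {p for ps in parents.values() for p in ps}
    ancestors = {}
    for term in all_terms:
        seen: set[str] = set()
        frontier = set(parents.get(term, set()))
        while frontier:
            seen |= frontier
            frontier = {
                gp for t in frontier for gp in parents.get(t, set())
            } - seen
        ancestors[term] = seen
    return ancestors


def simulate_annotation_bundle(
    config: SimulationConfig, truth: GroundTruth
) -> SyntheticBundle:
    """Toy OBO/GAF/slim/GMT/regulation bundle matched to the ground truth.

    The ontology is a fixed small DAG (>=3 levels, is_a and part_of); GAF
    annotations per protein draw terms uniformly from the process subtree and
    evidence codes from ``config.evidence_probs``; a few gene sets are
    enriched for the truly up-regulated proteins so enrichment has signal;
    the regulation table covers a sample of oocyte-expressed proteins.
    """
    if len(truth.frame) != config.n_proteins:
        raise ValueError("ground truth does not match config (protein count differs)")
    rng = np.random.default_rng(config.seed + 1)
    terms, edges = _toy_ontology()
    ancestors = _walk_ancestors(edges)
    slim_terms = [f"GO:10000{i:02d}" for i in range(1, len(_SLIM_NAMES) + 1)]
    bp_annotatable = [
        t for t, (_, ns, obs) in terms.items()
        if ns == "biological_process" and not obs and t != _BP_ROOT
    ]
    cc_annotatable = [
        t for t, (_, ns, obs) in terms.items()
        if ns == "cellular_component" and not obs and t != _CC_ROOT
    ]
    ev_codes = sorted(config.evidence_probs)
    ev_p = [config.evidence_probs[c] for c in ev_codes]

    gaf_rows: list[tuple] = []
    accessions = list(truth.frame["accession"])
    for acc in accessions:
        n_ann = int(rng.integers(config.min_annotations, config.max_annotations + 1))
        chosen = rng.choice(len(bp_annotatable), size=min(n_ann, len(bp_annotatable)),
                            replace=False)
        for t_idx in sorted(chosen):
            term = bp_annotatable[t_idx]
            evidence = ev_codes[int(rng.choice(len(ev_codes), p=ev_p))]
            gaf_rows.append(("GVC", acc, acc, "", term, evidence, "P"))
        if rng.random() < config.cc_annotation_prob and cc_annotatable:
            term = cc_annotatable[int(rng.integers(len(cc_annotatable)))]
            evidence = ev_codes[int(rng.choice(len(ev_codes), p=ev_p))]
            gaf_rows.append(("GVC", acc, acc, "", term, evidence, "C"))

    # gene sets: first three enriched for truly up-regulated proteins
    up = sorted(
        truth.frame.loc[
            truth.frame["differential"] & (truth.frame["direction"] == "higher"),
            "accession",
        ]
    )
    lo, hi = config.geneset_size_range
    hi = min(hi, config.n_proteins)
    lo = min(lo, hi)
    gene_sets: dict[str, set[str]] = {}
    for s in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if s < 3 and up:
            n_up = min(int(round(0.7 * size)), len(up))
            members = set(rng.choice(up, size=n_up, replace=False))
            rest = [a for a in accessions if a not in members]
            members |= set(rng.choice(rest, size=size - n_up, replace=False))
        else:
            members = set(rng.choice(accessions, size=size, replace=False))
        gene_sets[f"SET_{s:02d}"] = members

    oocyte_expressed = sorted(
        truth.frame.loc[
            truth.frame["membership"].isin(["common", "oocyte-only"]), "accession"
        ]
    )
    n_reg = int(round(config.regulation_frac * len(oocyte_expressed)))
    reg_accs = (
        rng.choice(oocyte_expressed, size=n_reg, replace=False) if n_reg else []
    )
    reg_rows = [
        {
            "accession": acc,
            "process_term": slim_terms[int(rng.integers(len(slim_terms)))],
            "direction": "agonist" if rng.random() < config.agonist_prob else "antagonist",
        }
        for acc in sorted(reg_accs)
    ]
    regulation = pd.DataFrame(reg_rows, columns=["accession", "process_term", "direction"])
    regulation = regulation.drop_duplicates(subset=["accession", "process_term"])

    return SyntheticBundle(
        terms=terms,
        edges=edges,
        ancestors=ancestors,
        slim_terms=slim_terms,
        gaf_rows=gaf_rows,
        gene_sets=gene_sets,
        regulation=regulation,
    )


def write_simulation(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Run both generators and write every file; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, truth = simulate_psm_tables(config)
    bundle = simulate_annotation_bundle(config, truth)
    paths = bundle.write(outdir)
    for sample, table in tables.items():
        path = outdir / f"psms_{sample}.tsv"
        write_psm_table(table, path)
        paths[f"psms_{sample}"] = path
    truth_path = outdir / "ground_truth.tsv"
    truth.write(truth_path)
    paths["ground_truth"] = truth_path
    return paths
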