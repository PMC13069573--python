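"""Information-content semantic similarity and term enrichment.

Works on any rooted is_a DAG with gene annotations (in the real study a
GO biological-process subgraph; here typically the synthetic ontology).

Information content follows the annotation-frequency definition with
the true-path rule: a gene annotated to a term counts for every
ancestor, p(t) is the fraction of annotated genes carrying t, and
IC(t) = −log p(t), normalized to [0, 1] by the maximum IC over
annotated terms.  Term similarity is the Jiang–Conrath measure on
normalized IC, sim = 1 − min(1, IC(t1) + IC(t2) − 2·IC(MICA)), where
MICA is the most informative common ancestor; gene-pair similarity
combines term similarities by best-match average (BMA).  Enrichment is
the one-sided hypergeometric upper tail with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .dupstats import GroupComparison, compare_groups

__all__ = [
    "OntologyDAG",
    "term_similarity",
    "gene_pair_similarity_bma",
    "pairwise_similarity",
    "enrich",
    "compare_divergent_similarity",
]


class OntologyDAG:
    """Rooted is_a DAG with gene annotations and information content.

    Parameters
    ----------
    edges : iterable of (child, parent) pairs
    annotations : mapping gene → set of directly annotated term ids
    """

    def __init__(self, edges, annotations: dict):
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)  # edge points child → parent
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("ontology contains a cycle")
        roots = [t for t in g.nodes if g.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValidationError(f"ontology must have one root, found {sorted(roots)}")
        self.root = roots[0]
        self.graph = g
        self.terms = set(g.nodes)
        for gene, terms in annotations.items():
            missing = set(terms) - self.terms
            if missing:
                raise ValidationError(
                    f"gene {gene!r} annotated to unknown terms {sorted(missing)}")
        self.annotations = {gene: frozenset(terms)
                            for gene, terms in annotations.items() if terms}
        # ancestor closure including the term itself (true-path rule)
        self._ancestors: dict[str, frozenset] = {
            t: frozenset(nx.descendants(g, t)) | {t} for t in g.nodes
        }
        self._compute_ic()

    def ancestors(self, term: str) -> frozenset:
        """Ancestors of ``term`` including itself."""
        return self._ancestors[term]

    def propagated(self, gene: str) -> frozenset:
        """A gene's annotation set propagated to all ancestors."""
        terms = self.annotations.get(gene, frozenset())
        out: set = set()
        for t in terms:
            out |= self._ancestors[t]
        return frozenset(out)

    def _compute_ic(self) -> None:
        counts: dict[str, int] = {t: 0 for t in self.terms}
        self.n_annotated_genes = len(self.annotations)
        for gene in self.annotations:
            for t in self.propagated(gene):
                counts[t] += 1
        self.term_counts = counts
        ic = {}
        n = self.n_annotated_genes
        for t, k in counts.items():
            ic[t] = -np.log(k / n) if (k > 0 and n > 0) else np.nan
        finite = [v for v in ic.values() if np.isfinite(v)]
        self._ic_max = max(finite) if finite else np.nan
        if self._ic_max and self._ic_max > 0:
            self.ic = {t: (v / self._ic_max if np.isfinite(v) else np.nan)
                       for t, v in ic.items()}
        else:
            self.ic = ic  # degenerate: every annotated term has IC 0
        self.ic[self.root] = 0.0

    def mica(self, t1: str, t2: str) -> str:
        """Most informative common ancestor (max normalized IC)."""
        common = self._ancestors[t1] & self._ancestors[t2]
        defined = [t for t in common if np.isfinite(self.ic.get(t, np.nan))]
        if not defined:
            raise ValidationError(f"no IC-defined common ancestor of {t1!r}, {t2!r}")
        # deterministic tie-break by term id
        return max(sorted(defined), key=lambda t: self.ic[t])


def term_similarity(t1: str, t2: str, dag: OntologyDAG,
                    measure: str = "jiang", form: str = "linear") -> float:
    """Similarity of two terms in [0, 1].

    ``measure='jiang'`` uses the IC distance d = IC(t1) + IC(t2) −
    2·IC(MICA); with ``form='linear'`` sim = 1 − min(1, d) (normalized
    IC keeps d in [0, 2]), with ``form='inverse'`` sim = 1/(1 + d).
    ``measure='resnik'`` returns IC(MICA) directly (already in [0, 1]
    after normalization).
    """
    for t in (t1, t2):
        if t not in dag.terms:
            raise ValidationError(f"term {t!r} not in ontology")
        if not np.isfinite(dag.ic.get(t, np.nan)):
            raise ValidationError(f"term {t!r} has undefined IC (no annotations)")
    ic_mica = dag.ic[dag.mica(t1, t2)]
    if measure == "resnik":
        return float(ic_mica)
    if measure != "jiang":
        raise ValueError(f"unknown measure {measure!r}")
    d = dag.ic[t1] + dag.ic[t2] - 2 * ic_mica
    if form == "linear":
        return float(1.0 - min(1.0, d))
    if form == "inverse":
        return float(1.0 / (1.0 + d))
    raise ValueError(f"unknown form {form!r}")


def gene_pair_similarity_bma(terms_a, terms_b, dag: OntologyDAG,
                             measure: str = "jiang",
                             form: str = "linear") -> float:
    """Best-match-average similarity of two annotation sets.

    Mean of each A-term's best similarity against B and vice versa,
    averaged.  Returns NaN when either set is empty (pair excluded by
    callers).
    """
    ta = [t for t in terms_a if np.isfinite(dag.ic.get(t, np.nan))]
    tb = [t for t in terms_b if np.isfinite(dag.ic.get(t, np.nan))]
    if not ta or not tb:
        return float("nan")
    sim = np.array([[term_similarity(a, b, dag, measure=measure, form=form)
                     for b in tb] for a in ta])
    return float((sim.max(axis=1).mean() + sim.max(axis=0).mean()) / 2.0)


def pairwise_similarity(pair_table: pd.DataFrame, dag: OntologyDAG,
                        measure: str = "jiang",
                        form: str = "linear") -> pd.DataFrame:
    """BMA similarity for each (gene_a, gene_b) row, from the DAG's
    direct annotations.  Unannotated pairs get NaN and are counted in
    ``attrs['n_unannotated']``."""
    sims = []
    for _, row in pair_table.iterrows():
        sims.append(gene_pair_similarity_bma(
            dag.annotations.get(row["gene_a"], frozenset()),
            dag.annotations.get(row["gene_b"], frozenset()),
            dag, measure=measure, form=form))
    out = pair_table.copy()
    out["similarity"] = sims
    out.attrs["n_unannotated"] = int(out["similarity"].isna().sum())
    return out


def enrich(study: set, background: set, dag: OntologyDAG,
           min_term_size: int = 10, fdr: float = 0.05) -> pd.DataFrame:
    """Hypergeometric term enrichment of a study set vs a background.

    Annotations are propagated to ancestors; terms with fewer than
    ``min_term_size`` background genes are excluded before testing.
    One-sided upper-tail p per term, Benjamini–Hochberg across tested
    terms; the returned table keeps terms with FDR ≤ ``fdr`` sorted by
    fold enrichment (= (k/n)/(K/N)) descending.
    """
    study = set(study)
    background = set(background)
    offenders = study - background
    if offenders:
        raise ValidationError(
            f"study genes not in background: {sorted(offenders)[:10]}")
    bg_by_term: dict[str, set] = {}
    for gene in background:
        for t in dag.propagated(gene):
            bg_by_term.setdefault(t, set()).add(gene)
    N, n = len(background), len(study)
    rows = []
    for term, bg_genes in sorted(bg_by_term.items()):
        K = len(bg_genes)
        if K < min_term_size:
            continue
        k = len(study & bg_genes)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else np.nan
        rows.append((term, k, n, K, N, fold, p))
    df = pd.DataFrame(rows, columns=["term", "study_count", "study_size",
                                     "background_count", "background_size",
                                     "fold_enrichment", "p"])
    if df.empty:
        df["fdr"] = []
        return df
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df[df["fdr"] <= fdr]
    return df.sort_values(["fold_enrichment", "term"],
                          ascending=[False, True]).reset_index(drop=True)


def compare_divergent_similarity(ssd_sim: pd.DataFrame, wgd_sim: pd.DataFrame
                                 ) -> GroupComparison:
    """Rank-sum contrast of SSD vs WGD pair similarities.

    Takes two outputs of :func:`pairwise_similarity` (typically the
    top-divergence selections) and reuses the group-comparison
    machinery on the pooled similarity samples.
    """
    ssd = ssd_sim["similarity"].dropna()
    wgd = wgd_sim["similarity"].dropna()
    scores = pd.concat([ssd, wgd], ignore_index=True)
    groups = pd.Series(["ssd"] * len(ssd) + ["wgd"] * len(wgd))
    return compare_groups(scores, groups, [("ssd", "wgd")])[0]
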