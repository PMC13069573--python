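"""Readers and writers for every table the pipeline touches.

All tables are TSV with a mandatory header row.  Gene identifiers are
opaque strings (AGI-style ``AT1G01010`` in real data, arbitrary in
tests).  Expression panels use composite column names
``<individual>__<timepoint>``; the ``__`` separator is reserved and must
appear exactly once per expression column.

Missing values are written as empty fields and read back as missing —
readers never silently coerce a missing cell to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionPanel",
    "ConditionAtlas",
    "ParalogTable",
    "MODES",
    "ORIENTATIONS",
    "STATUSES",
    "read_expression_panel",
    "write_expression_panel",
    "read_atlas",
    "write_atlas",
    "read_paralog_table",
    "write_paralog_table",
    "read_gene_meta",
    "write_gene_meta",
    "read_ontology_files",
    "write_ontology_files",
    "write_results",
    "load_config",
    "write_run_log",
]

MODES = frozenset({"wgd", "tandem", "proximal", "transposed", "dispersed"})
ORIENTATIONS = frozenset({"A_is_parent", "B_is_parent", "unknown"})
STATUSES = frozenset({"singleton", "ssd", "wgd"})

N_CLADES = 15


class FormatError(ValueError):
    """A file does not follow the documented TSV layout."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


# ---------------------------------------------------------------------------
# ExpressionPanel
# ---------------------------------------------------------------------------


@dataclass
class ExpressionPanel:
    """Gene × individual × timepoint nonnegative expression tensor.

    ``values`` has shape ``(n_genes, n_individuals, n_timepoints)`` with
    NaN marking missing cells.  Individuals and timepoints are kept in
    sorted order so panels built from column-permuted files compare equal.
    """

    genes: list[str]
    individuals: list[str]
    timepoints: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.genes), len(self.individuals), len(self.timepoints))
        if self.values.shape != expected:
            raise ValidationError(
                f"panel values shape {self.values.shape} != {expected}"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers in panel")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValidationError("negative expression value in panel")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def timepoint_matrix(self, timepoint: str) -> np.ndarray:
        """Gene × individual slice for one timepoint (NaN = missing)."""
        t = self.timepoints.index(timepoint)
        return self.values[:, :, t]

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for i, ind in enumerate(self.individuals):
            for t, tp in enumerate(self.timepoints):
                cols[f"{ind}__{tp}"] = self.values[:, i, t]
        return pd.DataFrame(cols, index=pd.Index(self.genes, name="gene"))

    def equals(self, other: "ExpressionPanel") -> bool:
        return (
            self.genes == other.genes
            and self.individuals == other.individuals
            and self.timepoints == other.timepoints
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def read_expression_panel(path: str | Path) -> ExpressionPanel:
    """Read a panel TSV: first column gene id, then ``ind__tp`` columns.

    A combination (individual, timepoint) absent from the header, or an
    empty field, is recorded as missing.  Negative values raise
    :class:`ValidationError` naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str},
                     float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene column plus expression columns")
    gene_col = df.columns[0]
    parsed: list[tuple[str, str, str]] = []
    for col in df.columns[1:]:
        parts = col.split("__")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise FormatError(
                f"{path}: column {col!r} is not of the form <individual>__<timepoint>"
            )
        parsed.append((col, parts[0], parts[1]))

    genes = df[gene_col].astype(str).tolist()
    if len(set(genes)) != len(genes):
        dup = pd.Series(genes)
        dup = dup[dup.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene identifier {dup!r}")

    individuals = sorted({ind for _, ind, _ in parsed})
    timepoints = sorted({tp for _, _, tp in parsed})
    values = np.full((len(genes), len(individuals), len(timepoints)), np.nan)
    ind_ix = {v: i for i, v in enumerate(individuals)}
    tp_ix = {v: i for i, v in enumerate(timepoints)}
    for col, ind, tp in parsed:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"at gene {genes[row]!r}, column {col!r}"
            )
        neg = vals < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise ValidationError(
                f"{path}: negative value {vals.iloc[row]} "
                f"at gene {genes[row]!r}, column {col!r}"
            )
        values[:, ind_ix[ind], tp_ix[tp]] = vals.to_numpy()
    return ExpressionPanel(genes, individuals, timepoints, values)


def write_expression_panel(panel: ExpressionPanel, path: str | Path) -> Path:
    path = Path(path)
    panel.to_frame().to_csv(path, sep="\t", float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# ConditionAtlas
# ---------------------------------------------------------------------------


@dataclass
class ConditionAtlas:
    """Expression atlas: genes × samples, with per-sample metadata.

    ``samples`` is indexed by sample id with columns ``tissue``,
    ``treatment``, ``baseline`` (the linked baseline sample id, or NaN
    for baseline samples) and ``ecotype``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing_meta = [c for c in ("tissue", "treatment", "baseline", "ecotype")
                        if c not in self.samples.columns]
        if missing_meta:
            raise FormatError(f"atlas sample table lacks columns {missing_meta}")
        unknown = set(self.values.columns) - set(self.samples.index)
        if unknown:
            raise ValidationError(f"atlas samples without metadata: {sorted(unknown)}")
        for sid, link in self.samples["baseline"].items():
            if pd.isna(link):
                continue
            if link not in self.samples.index:
                raise ValidationError(
                    f"sample {sid!r}: baseline link {link!r} does not resolve"
                )
            if not pd.isna(self.samples.loc[link, "baseline"]):
                raise ValidationError(
                    f"sample {sid!r}: baseline {link!r} itself links to a baseline"
                )
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise ValidationError("negative expression value in atlas")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def treatment_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["baseline"].notna()]

    def tissue_samples(self) -> pd.DataFrame:
        """Untreated samples, one expression column per tissue."""
        return self.samples[self.samples["baseline"].isna()
                            & self.samples["treatment"].isna()]

    def equals(self, other: "ConditionAtlas") -> bool:
        try:
            pd.testing.assert_frame_equal(self.values, other.values)
            pd.testing.assert_frame_equal(self.samples, other.samples)
        except AssertionError:
            return False
        return True


def read_atlas(values_path: str | Path, samples_path: str | Path) -> ConditionAtlas:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0,
                          dtype={"tissue": str, "treatment": str,
                                 "baseline": str, "ecotype": str})
    samples.index = samples.index.astype(str)
    return ConditionAtlas(values, samples)


def write_atlas(atlas: ConditionAtlas, values_path: str | Path,
                samples_path: str | Path) -> tuple[Path, Path]:
    atlas.values.to_csv(values_path, sep="\t")
    atlas.samples.to_csv(samples_path, sep="\t")
    return Path(values_path), Path(samples_path)


# ---------------------------------------------------------------------------
# ParalogTable
# ---------------------------------------------------------------------------


@dataclass
class ParalogTable:
    """Gene pairs with duplication mode, orientation and optional Ks.

    SSD is defined as any non-WGD mode (tandem, proximal, transposed,
    dispersed).
    """

    pairs: pd.DataFrame  # columns: gene_a, gene_b, mode, orientation, ks

    def __post_init__(self) -> None:
        required = {"gene_a", "gene_b", "mode"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise FormatError(f"paralog table lacks columns {sorted(missing)}")
        df = self.pairs.copy()
        if "orientation" not in df.columns:
            df["orientation"] = "unknown"
        df["orientation"] = df["orientation"].fillna("unknown")
        if "ks" not in df.columns:
            df["ks"] = np.nan
        bad_mode = ~df["mode"].isin(MODES)
        if bad_mode.any():
            offender = df.loc[bad_mode, "mode"].iloc[0]
            raise ValidationError(
                f"unknown duplication mode {offender!r}; allowed: {sorted(MODES)}"
            )
        bad_orient = ~df["orientation"].isin(ORIENTATIONS)
        if bad_orient.any():
            offender = df.loc[bad_orient, "orientation"].iloc[0]
            raise ValidationError(
                f"unknown orientation {offender!r}; allowed: {sorted(ORIENTATIONS)}"
            )
        if (df["gene_a"] == df["gene_b"]).any():
            gene = df.loc[df["gene_a"] == df["gene_b"], "gene_a"].iloc[0]
            raise ValidationError(f"self-pair for gene {gene!r}")
        with np.errstate(invalid="ignore"):
            if (df["ks"].to_numpy(dtype=float) < 0).any():
                raise ValidationError("negative Ks value")
        self.pairs = df.reset_index(drop=True)

    @property
    def is_ssd(self) -> pd.Series:
        return self.pairs["mode"] != "wgd"

    def subset(self, modes) -> "ParalogTable":
        modes = set(modes)
        return ParalogTable(self.pairs[self.pairs["mode"].isin(modes)].copy())

    def equals(self, other: "ParalogTable") -> bool:
        try:
            pd.testing.assert_frame_equal(self.pairs, other.pairs)
        except AssertionError:
            return False
        return True


def read_paralog_table(path: str | Path) -> ParalogTable:
    df = pd.read_csv(path, sep="\t",
                     dtype={"gene_a": str, "gene_b": str, "mode": str})
    if "orientation" in df.columns:
        df["orientation"] = df["orientation"].astype("string").astype(object)
        df.loc[df["orientation"].isna(), "orientation"] = np.nan
    return ParalogTable(df)


def write_paralog_table(table: ParalogTable, path: str | Path) -> Path:
    table.pairs.to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# GeneMeta
# ---------------------------------------------------------------------------


def _parse_terms(value) -> frozenset:
    if pd.isna(value) or value == "":
        return frozenset()
    return frozenset(str(value).split("|"))


def validate_gene_meta(df: pd.DataFrame) -> pd.DataFrame:
    required = {"status", "clade", "is_tf", "go_terms", "mean_expression"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene meta lacks columns {sorted(missing)}")
    bad = ~df["status"].isin(STATUSES)
    if bad.any():
        offender = df.loc[bad, "status"].iloc[0]
        raise ValidationError(
            f"unknown duplication status {offender!r}; allowed: {sorted(STATUSES)}"
        )
    clade = df["clade"]
    defined = clade.notna()
    if defined.any():
        vals = clade[defined].astype(float)
        if ((vals < 1) | (vals > N_CLADES) | (vals != vals.round())).any():
            offender = vals[(vals < 1) | (vals > N_CLADES) | (vals != vals.round())].iloc[0]
            raise ValidationError(
                f"clade {offender!r} outside integer range 1..{N_CLADES}"
            )
    return df


def read_gene_meta(path: str | Path) -> pd.DataFrame:
    """Per-gene metadata, indexed by gene id.

    Columns: ``status`` (singleton/ssd/wgd), ``clade`` (1..15 or
    missing), ``is_tf`` (bool), ``go_terms`` (frozenset, ``|``-joined on
    disk), ``mean_expression`` (float or missing).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df["is_tf"] = df["is_tf"].astype(bool)
    df["go_terms"] = df["go_terms"].map(_parse_terms) if "go_terms" in df else frozenset()
    df["clade"] = pd.to_numeric(df.get("clade"), errors="coerce")
    df["mean_expression"] = pd.to_numeric(df.get("mean_expression"), errors="coerce")
    return validate_gene_meta(df)


def write_gene_meta(meta: pd.DataFrame, path: str | Path) -> Path:
    out = meta.copy()
    out["go_terms"] = out["go_terms"].map(lambda s: "|".join(sorted(s)))
    out.to_csv(path, sep="\t")
    return Path(path)


# ---------------------------------------------------------------------------
# Ontology file pair
# ---------------------------------------------------------------------------


def read_ontology_files(edges_path: str | Path,
                        annotations_path: str | Path
                        ) -> tuple[pd.DataFrame, dict[str, frozenset]]:
    """Read the (edges, annotations) TSV pair.

    Edges: one ``child<TAB>parent`` is_a edge per row.  Annotations: one
    ``gene<TAB>term`` row per direct annotation.  DAG invariants (single
    root, acyclicity) are enforced by :class:`exprvar.ontology.OntologyDAG`.
    """
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    if list(edges.columns[:2]) != ["child", "parent"]:
        raise FormatError(
            f"{edges_path}: expected columns child, parent; got {list(edges.columns)}"
        )
    ann = pd.read_csv(annotations_path, sep="\t", dtype=str)
    if list(ann.columns[:2]) != ["gene", "term"]:
        raise FormatError(
            f"{annotations_path}: expected columns gene, term; got {list(ann.columns)}"
        )
    annotations = {
        gene: frozenset(group["term"]) for gene, group in ann.groupby("gene")
    }
    return edges, annotations


def write_ontology_files(edges: pd.DataFrame, annotations: dict,
                         edges_path: str | Path,
                         annotations_path: str | Path) -> tuple[Path, Path]:
    edges[["child", "parent"]].to_csv(edges_path, sep="\t", index=False)
    rows = [(g, t) for g in sorted(annotations) for t in sorted(annotations[g])]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(
        annotations_path, sep="\t", index=False)
    return Path(edges_path), Path(annotations_path)


# ---------------------------------------------------------------------------
# Generic results / config / run log
# ---------------------------------------------------------------------------


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  index: bool = False) -> dict[str, Path]:
    """Write each named table to ``<out_dir>/<name>.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        paths[name] = p
    return paths


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def write_run_log(out_dir: str | Path, command: str, params: dict) -> Path:
    """Record the parameters (incl. seed and RNG algorithm) of a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_log.yaml"
    entry = {"command": command, "rng": "numpy PCG64 (default_rng)",
             "params": {k: (v if not isinstance(v, Path) else str(v))
                        for k, v in params.items()}}
    with open(path, "a") as fh:
        yaml.safe_dump([entry], fh, sort_keys=False)
    return path
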