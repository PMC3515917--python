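"""Readers, writers and preprocessing for the pipeline's external formats.

The pipeline operates on four kinds of input:

* a log2 expression matrix (genes x samples, TSV) with a sample sheet pairing
  each sample to a patient and a condition (``MC`` = melanocytes from normal
  skin, ``DNMC`` = melanocytes from a dysplastic naevus);
* gene-set annotations (two-column TSV or GAF 2.x) with an optional OBO
  ontology for ancestor propagation;
* a 2D-DIGE spot-volume table (long CSV, one row per spot/gel-set/channel);
* a qPCR Ct table (long CSV, one row per replicate measurement).

All readers validate the structural invariants the downstream statistics rely
on — paired completeness of the design, uniqueness of identifiers, finiteness
of values — and raise informative errors naming the offending record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("naevus_omics")

#: The two conditions of the paired design.
CONDITIONS = ("MC", "DNMC")

#: Channel order used throughout the DIGE arrays: index 0 = MC, 1 = DNMC.
CHANNELS = ("MC", "DNMC")

#: GO namespaces, as abbreviated in result tables.
NAMESPACES = ("BP", "MF", "CC")

_NAMESPACE_ABBREV = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


def setup_logging(level: int = logging.INFO) -> None:
    """Configure the package logger with a timestamped stream handler."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a YAML mapping")
    return cfg


def log_run_context(seed: int | None, params: Mapping) -> None:
    """Log seed, package versions and the parameter set of a run."""
    import scipy

    from . import __version__

    logger.info(
        "run context: seed=%s naevus-omics=%s numpy=%s scipy=%s pandas=%s",
        seed, __version__, np.__version__, scipy.__version__, pd.__version__,
    )
    logger.info("parameters: %s", dict(params))


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with paired design metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per sample ID, holding
        log2 expression values.
    sample_sheet
        DataFrame indexed by sample ID with columns ``patient_id`` and
        ``condition`` (one of ``MC``/``DNMC``).

    Every patient in the sheet must contribute exactly one MC and one DNMC
    sample (paired completeness); the constructor enforces this.
    """

    values: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.sample_sheet = self.sample_sheet.copy()
        self.validate()

    # -- accessors ----------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid in self.sample_sheet["patient_id"]:
            seen.setdefault(pid)
        return list(seen)

    @property
    def n_pairs(self) -> int:
        return len(self.patient_ids)

    def sample_for(self, patient_id: str, condition: str) -> str:
        """Return the sample ID of `patient_id`'s `condition` sample."""
        sheet = self.sample_sheet
        hit = sheet[(sheet["patient_id"] == patient_id) & (sheet["condition"] == condition)]
        if len(hit) != 1:
            raise KeyError(f"no unique {condition} sample for patient {patient_id!r}")
        return str(hit.index[0])

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        vals = self.values
        sheet = self.sample_sheet
        if vals.index.duplicated().any():
            dup = vals.index[vals.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if vals.columns.duplicated().any():
            dup = vals.columns[vals.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        missing_cols = {"patient_id", "condition"} - set(sheet.columns)
        if missing_cols:
            raise ValueError(f"sample sheet lacks columns: {sorted(missing_cols)}")
        unknown = set(vals.columns) - set(sheet.index)
        if unknown:
            raise ValueError(
                f"samples in matrix but absent from sample sheet: {sorted(unknown)}"
            )
        bad_cond = sheet.loc[~sheet["condition"].isin(CONDITIONS)]
        if len(bad_cond):
            raise ValueError(
                f"unknown condition {bad_cond['condition'].iloc[0]!r} "
                f"for sample {bad_cond.index[0]!r}"
            )
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        # paired completeness: each patient has exactly one MC and one DNMC
        counts = sheet.groupby(["patient_id", "condition"], sort=False).size()
        for pid in sheet["patient_id"].unique():
            for cond in CONDITIONS:
                n = counts.get((pid, cond), 0)
                if n != 1:
                    raise ValueError(
                        f"patient {pid!r} has {n} {cond} samples; "
                        "paired design requires exactly one"
                    )


def read_expression(matrix_path: str | Path, sheet_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV and its sample sheet into an ExpressionMatrix.

    The matrix TSV must have a header row of sample IDs and a first column of
    gene IDs; the sheet TSV must have columns ``sample_id``, ``patient_id``
    and ``condition``.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    non_numeric = values.columns[
        [not np.issubdtype(dt, np.number) for dt in values.dtypes]
    ]
    if len(non_numeric):
        raise ValueError(
            f"non-numeric expression values in sample column {non_numeric[0]!r}"
        )
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "condition"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample ID in sheet: {dup!r}")
    sheet = sheet.set_index("sample_id")
    # restrict the sheet to samples actually in the matrix (extra rows allowed)
    sheet = sheet.loc[[s for s in sheet.index if s in set(values.columns)]]
    return ExpressionMatrix(values=values.astype(float), sample_sheet=sheet)


def write_expression(
    matrix: ExpressionMatrix, matrix_path: str | Path, sheet_path: str | Path
) -> None:
    """Write an ExpressionMatrix back to matrix + sample-sheet TSVs.

    Uses full float precision so a write/read round trip is bit-exact.
    """
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id",
                         float_format=None)
    matrix.sample_sheet.to_csv(sheet_path, sep="\t", index_label="sample_id")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize sample columns to a common distribution.

    Every column is mapped onto the reference distribution formed by the
    row-wise mean of the sorted columns, so afterwards all columns hold the
    identical multiset of values. Ties within a column receive the mean of
    the reference values they span (the standard dialect). Gene and sample
    order are preserved.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("quantile normalization requires finite values")
    from scipy.stats import rankdata

    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        # integer ranks index the reference directly; half ranks (ties over an
        # even span) interpolate between adjacent reference values
        out[:, j] = np.interp(ranks, grid, reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=values, sample_sheet=matrix.sample_sheet)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    term_id: str
    name: str
    namespace: str  # "BP" | "MF" | "CC" | "unknown"
    genes: frozenset


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms) together with the analysis gene universe."""

    sets: dict = field(default_factory=dict)  # term_id -> GeneSet
    universe: frozenset | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.sets

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def with_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Return a copy with the gene universe set (members not restricted)."""
        return GeneSetCollection(sets=dict(self.sets), universe=frozenset(universe))

    def members_in_universe(self, term_id: str) -> frozenset:
        if self.universe is None:
            raise ValueError("collection has no universe set")
        return self.sets[term_id].genes & self.universe


def _parse_two_column_tsv(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pairs.append((fields[0], fields[1]))
    return pairs


def _parse_gaf(path: str | Path) -> list[tuple[str, str]]:
    # GAF 2.x: column 2 = DB object symbol's ID, column 4 = qualifier,
    # column 5 = GO ID. NOT-qualified rows are negative annotations: dropped.
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                continue
            pairs.append((fields[1], fields[4]))
    return pairs


def read_gene_sets(
    annotation_path: str | Path,
    obo_path: str | Path | None = None,
    propagate: bool = True,
) -> GeneSetCollection:
    """Read gene->term annotations into a GeneSetCollection.

    `annotation_path` is either a GAF 2.x file (detected by the ``!gaf-version``
    header or a ``.gaf`` suffix) or a plain two-column gene<TAB>term TSV.
    When `obo_path` is given the ontology's ``is_a`` graph supplies term
    names and namespaces, and — with `propagate` — every gene annotated to a
    term is also made a member of all of that term's ancestors.
    """
    path = Path(annotation_path)
    with open(path) as fh:
        first = fh.readline()
    is_gaf = path.suffix.lower() == ".gaf" or first.startswith("!gaf-version")
    pairs = _parse_gaf(path) if is_gaf else _parse_two_column_tsv(path)

    term_names: dict[str, str] = {}
    term_ns: dict[str, str] = {}
    ancestors: dict[str, set] = {}
    if obo_path is not None:
        import networkx as nx
        import obonet

        graph = obonet.read_obo(obo_path)
        # keep only is_a edges (obonet edges run child -> parent, keyed by
        # relation type)
        isa = nx.DiGraph()
        isa.add_nodes_from(graph.nodes)
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                isa.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(isa):
            raise ValueError("cyclic is_a graph in OBO file")
        for node, data in graph.nodes(data=True):
            term_names[node] = data.get("name", node)
            term_ns[node] = _NAMESPACE_ABBREV.get(data.get("namespace", ""), "unknown")
        for term in isa.nodes:
            ancestors[term] = nx.descendants(isa, term)  # all is_a ancestors

    membership: dict[str, set] = {}
    for gene, term in pairs:
        if obo_path is not None and term not in term_names:
            warnings.warn(
                f"annotation term {term!r} absent from OBO; kept as namespace-unknown"
            )
        membership.setdefault(term, set()).add(gene)
        if propagate and term in ancestors:
            for anc in ancestors[term]:
                membership.setdefault(anc, set()).add(gene)

    sets = {
        term: GeneSet(
            term_id=term,
            name=term_names.get(term, term),
            namespace=term_ns.get(term, "unknown"),
            genes=frozenset(genes),
        )
        for term, genes in membership.items()
    }
    return GeneSetCollection(sets=sets, universe=None)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as a two-column gene<TAB>term TSV (sorted, stable)."""
    with open(path, "w") as fh:
        for term_id in sorted(collection.sets):
            for gene in sorted(collection.sets[term_id].genes):
                fh.write(f"{gene}\t{term_id}\n")


# ---------------------------------------------------------------------------
# DIGE spot tables
# ---------------------------------------------------------------------------

@dataclass
class SpotTable:
    """2D-DIGE spot volumes for a set of paired gels.

    `volumes` has shape (n_spots, n_gel_sets, 2) with channel axis ordered
    (MC, DNMC); entries where `present` is False are NaN. `present` has shape
    (n_spots, n_gel_sets): a spot is present on a gel set only when both
    channels were quantified. `dye_swap` flags gel sets run with the dye
    assignment exchanged (Cy3 on the lesional sample).
    """

    spot_ids: list
    gel_set_ids: list
    volumes: np.ndarray
    present: np.ndarray
    dye_swap: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        self.dye_swap = np.asarray(self.dye_swap, dtype=bool)
        S, G = len(self.spot_ids), len(self.gel_set_ids)
        if self.volumes.shape != (S, G, 2):
            raise ValueError(f"volumes shape {self.volumes.shape} != {(S, G, 2)}")
        if self.present.shape != (S, G):
            raise ValueError(f"present shape {self.present.shape} != {(S, G)}")
        if self.dye_swap.shape != (G,):
            raise ValueError(f"dye_swap shape {self.dye_swap.shape} != {(G,)}")
        present3 = np.repeat(self.present[:, :, None], 2, axis=2)
        vols = self.volumes[present3]
        if vols.size and (not np.isfinite(vols).all() or (vols < 0).any()):
            raise ValueError("present volumes must be finite and non-negative")
        if np.isfinite(self.volumes[~present3]).any():
            raise ValueError("absent cells must hold NaN volumes")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_gel_sets(self) -> int:
        return len(self.gel_set_ids)

    def copy_with(self, volumes: np.ndarray) -> "SpotTable":
        return SpotTable(
            spot_ids=list(self.spot_ids),
            gel_set_ids=list(self.gel_set_ids),
            volumes=volumes,
            present=self.present.copy(),
            dye_swap=self.dye_swap.copy(),
        )


def read_spot_table(path: str | Path) -> SpotTable:
    """Read a long-format spot CSV: spot_id, gel_set_id, channel, volume, dye, present."""
    df = pd.read_csv(path, dtype={"spot_id": str, "gel_set_id": str})
    required = {"spot_id", "gel_set_id", "channel", "volume", "present"}
    if not required.issubset(df.columns):
        raise ValueError(f"spot CSV must have columns {sorted(required)}")
    spot_ids = list(dict.fromkeys(df["spot_id"]))
    gel_ids = list(dict.fromkeys(df["gel_set_id"]))
    s_idx = {s: i for i, s in enumerate(spot_ids)}
    g_idx = {g: i for i, g in enumerate(gel_ids)}
    volumes = np.full((len(spot_ids), len(gel_ids), 2), np.nan)
    present = np.zeros((len(spot_ids), len(gel_ids)), dtype=bool)
    dye_swap = np.zeros(len(gel_ids), dtype=bool)
    if "dye_swap" in df.columns:
        for g, flag in zip(df["gel_set_id"], df["dye_swap"]):
            dye_swap[g_idx[g]] = bool(flag)
    pres_count = np.zeros((len(spot_ids), len(gel_ids)), dtype=int)
    for row in df.itertuples(index=False):
        c = CHANNELS.index(row.channel)
        i, j = s_idx[row.spot_id], g_idx[row.gel_set_id]
        if bool(row.present):
            volumes[i, j, c] = float(row.volume)
            pres_count[i, j] += 1
    present = pres_count == 2  # present only when both channels quantified
    volumes[~np.repeat(present[:, :, None], 2, axis=2)] = np.nan
    return SpotTable(spot_ids, gel_ids, volumes, present, dye_swap)


def write_spot_table(table: SpotTable, path: str | Path) -> None:
    rows = []
    for i, sid in enumerate(table.spot_ids):
        for j, gid in enumerate(table.gel_set_ids):
            for c, channel in enumerate(CHANNELS):
                rows.append(
                    {
                        "spot_id": sid,
                        "gel_set_id": gid,
                        "channel": channel,
                        "volume": table.volumes[i, j, c],
                        "present": bool(table.present[i, j]),
                        "dye_swap": bool(table.dye_swap[j]),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Long-format qPCR Ct measurements.

    `data` has columns patient_id, sample (MC/DNMC), gene, replicate, ct.
    Every (patient, sample, gene) cell must carry at least one replicate with
    a positive, finite Ct.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"patient_id", "sample", "gene", "replicate", "ct"}
        if not required.issubset(df.columns):
            raise ValueError(f"Ct table must have columns {sorted(required)}")
        ct = df["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("Ct values must be positive and finite")
        bad = df.loc[~df["sample"].isin(CONDITIONS)]
        if len(bad):
            raise ValueError(f"unknown sample condition {bad['sample'].iloc[0]!r}")

    def mean_ct(self, patient_id, sample: str, gene: str) -> float:
        """Replicate-averaged Ct for one (patient, condition, gene) cell."""
        df = self.data
        sel = df[
            (df["patient_id"] == patient_id)
            & (df["sample"] == sample)
            & (df["gene"] == gene)
        ]
        if sel.empty:
            raise KeyError(
                f"no Ct measurements for patient={patient_id!r} "
                f"sample={sample!r} gene={gene!r}"
            )
        return float(sel["ct"].mean())

    @property
    def patients(self) -> list:
        return list(dict.fromkeys(self.data["patient_id"]))

    @property
    def genes(self) -> list:
        return list(dict.fromkeys(self.data["gene"]))


def read_ct_table(path: str | Path) -> CtTable:
    df = pd.read_csv(path, dtype={"patient_id": str, "gene": str})
    return CtTable(data=df)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)
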