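"""Input parsing, validation, and assembly of miRNA–gene-set modules.

All inputs are plain text: expression matrices as TSV (feature rows, sample
columns), gene sets as GMT (the MSigDB exchange format), miRNA→target
interactions and sample→condition assignments as two-column TSV.  Gene and
miRNA identifiers are matched by exact, case-sensitive string equality —
inputs are expected to share one identifier namespace, and no alias
resolution is attempted.

A *module* is a gene set (protein complex or pathway) restricted to the
genes measured in the mRNA matrix, together with every measured miRNA that
targets at least one surviving member.  Gene sets that end up smaller than
``min_complex_size`` or that are targeted by no measured miRNA do not form
modules and are reported (not raised) with their exclusion reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleGroups",
    "InteractionSet",
    "GeneSet",
    "GeneSetCollection",
    "ModuleDefinition",
    "ConditionData",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_interactions",
    "write_interactions",
    "read_groups",
    "write_groups",
    "build_modules",
    "align_conditions",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features × samples expression matrix on a continuous scale.

    Values are used exactly as provided (normalization and log-transformation
    are upstream concerns).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at feature "
                f"{self.feature_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        self._row_index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._row_index

    def profile(self, feature_id: str) -> np.ndarray:
        """Expression vector of one feature across samples."""
        try:
            return self.values[self._row_index[feature_id]]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in expression matrix") from None

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        col_index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [col_index[s] for s in sample_ids]
        return ExpressionMatrix(list(self.feature_ids), list(sample_ids), self.values[:, cols])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SampleGroups:
    """Mapping sample ID → condition label."""

    assignment: dict

    def conditions(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.assignment.items() if c == condition]


@dataclass(frozen=True)
class InteractionSet:
    """Directed miRNA → target-gene interaction edges."""

    edges: frozenset

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if not m or not g:
                raise ValueError(f"interaction with empty identifier: ({m!r}, {g!r})")

    def __len__(self) -> int:
        return len(self.edges)

    def mirnas_targeting(self, genes) -> set:
        genes = set(genes)
        return {m for m, g in self.edges if g in genes}

    def gene_to_mirnas(self) -> dict:
        adj: dict = {}
        for m, g in self.edges:
            adj.setdefault(g, set()).add(m)
        return adj


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: tuple

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.set_id!r} has duplicate members")
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list

    def __post_init__(self) -> None:
        _check_unique([s.set_id for s in self.sets], "gene set")
        self._index = {s.set_id: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._index[set_id]


@dataclass(frozen=True)
class ModuleDefinition:
    """An analyzable module: measured complex members plus targeting miRNAs.

    ``proteins`` are the gene-set members present in the mRNA matrix;
    ``mirnas`` are the measured miRNAs targeting at least one of them.  The
    module matrix built later covers *every* (protein, miRNA) cell: a miRNA
    targeting one member is treated as influencing the whole complex, so no
    distinction is made between targeted and untargeted members.
    """

    set_id: str
    proteins: tuple
    mirnas: tuple
    set_name: str = ""

    def __post_init__(self) -> None:
        if len(self.proteins) < 2:
            raise ValueError(f"module {self.set_id!r} has fewer than 2 proteins")
        if len(self.mirnas) < 1:
            raise ValueError(f"module {self.set_id!r} has no targeting miRNA")


@dataclass(frozen=True)
class ConditionData:
    """mRNA and miRNA matrices restricted to one condition's matched samples."""

    condition: str
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.mrna.sample_ids != self.mirna.sample_ids:
            raise ValueError("mRNA and miRNA sample orders differ within a condition")

    @property
    def n_samples(self) -> int:
        return self.mrna.n_samples


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} IDs: {sorted(set(dups))}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature IDs, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate feature IDs: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValueError(f"{path}: duplicate sample IDs: {dups}")
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        try:
            # astype(float) parses through Python's exact float() conversion
            values[:, j] = df[col].astype(float)
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at feature "
                f"{bad.index[0]!r}, sample {col!r}"
            ) from None
    matrix = ExpressionMatrix(list(df.index), list(df.columns), values)
    logger.info("read %d features x %d samples from %s",
                matrix.n_features, matrix.n_samples, path)
    return matrix


def write_expression(matrix: ExpressionMatrix, path) -> None:
    # repr() of a Python float is the shortest exact round-trip form
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from GMT: ``set_id TAB description TAB member...``.

    Duplicate members within a line are collapsed with a warning; lines with
    fewer than three fields are a parse error.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields; "
                    "expected set_id, description, members..."
                )
            set_id, name, raw_members = fields[0], fields[1], fields[2:]
            members, seen = [], set()
            for m in raw_members:
                if not m:
                    continue
                if m in seen:
                    logger.warning("%s:%d: duplicate member %r in set %r dropped",
                                   path, lineno, m, set_id)
                    continue
                seen.add(m)
                members.append(m)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            sets.append(GeneSet(set_id, name, tuple(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.name, *s.members]) + "\n")


def read_interactions(path) -> InteractionSet:
    """Read a two-column miRNA→gene TSV; a header containing 'mirna' is skipped."""
    edges = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty interaction file")
    start = 1 if "mirna" in lines[0].lower() else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        edges.append((fields[0], fields[1]))
    unique = frozenset(edges)
    if len(unique) < len(edges):
        logger.info("%s: collapsed %d duplicate interaction rows",
                    path, len(edges) - len(unique))
    return InteractionSet(unique)


def write_interactions(interactions: InteractionSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for m, g in sorted(interactions.edges):
            fh.write(f"{m}\t{g}\n")


def read_groups(path) -> SampleGroups:
    """Read a two-column sample→condition TSV (header detected by 'sample')."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty sample-group file")
    start = 1 if "sample" in lines[0].lower() else 0
    assignment: dict = {}
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        sample, condition = fields[0], fields[1]
        if sample in assignment:
            raise ValueError(f"{path}:{lineno}: sample {sample!r} assigned twice")
        assignment[sample] = condition
    return SampleGroups(assignment)


def write_groups(groups: SampleGroups, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\n")
        for s, c in groups.assignment.items():
            fh.write(f"{s}\t{c}\n")


# ---------------------------------------------------------------------------
# module assembly
# ---------------------------------------------------------------------------

def build_modules(
    gene_sets: GeneSetCollection,
    interactions: InteractionSet,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    min_complex_size: int = 2,
):
    """Assemble analyzable modules from gene sets, interactions and data.

    For each gene set, members are intersected with the measured mRNA
    features; all measured miRNAs targeting at least one surviving member
    are collected.  Sets smaller than ``min_complex_size`` after the
    intersection, or with no targeting miRNA, are excluded and reported.

    Returns
    -------
    (modules, report)
        ``modules``: list of :class:`ModuleDefinition` (member and miRNA
        lists sorted, so output is invariant to input ordering).
        ``report``: DataFrame with columns set_id, status, reason,
        n_proteins, n_mirnas covering every input set.
    """
    if min_complex_size < 2:
        raise ValueError("min_complex_size must be >= 2")
    measured_mirnas = set(mirna.feature_ids)
    modules, rows = [], []
    for gs in gene_sets:
        proteins = sorted(m for m in gs.members if m in mrna)
        mirnas = sorted(
            interactions.mirnas_targeting(proteins) & measured_mirnas
        )
        if len(proteins) < min_complex_size:
            rows.append((gs.set_id, "excluded",
                         f"size after intersection < {min_complex_size}",
                         len(proteins), len(mirnas)))
            continue
        if not mirnas:
            rows.append((gs.set_id, "excluded", "no targeting miRNA",
                         len(proteins), 0))
            continue
        modules.append(ModuleDefinition(gs.set_id, tuple(proteins), tuple(mirnas),
                                        set_name=gs.name))
        rows.append((gs.set_id, "included", "", len(proteins), len(mirnas)))
    report = pd.DataFrame(
        rows, columns=["set_id", "status", "reason", "n_proteins", "n_mirnas"]
    )
    n_excluded = int((report["status"] == "excluded").sum())
    logger.info("assembled %d modules (%d sets excluded)", len(modules), n_excluded)
    return modules, report


def align_conditions(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    groups: SampleGroups,
    condition_a: str,
    condition_b: str,
    min_samples: int = 3,
):
    """Restrict both matrices to each condition's matched samples.

    Only samples present in *both* matrices and labeled with one of the two
    conditions are kept; within each condition the mRNA and miRNA matrices
    get the identical, identically-ordered sample set (mRNA column order).
    Fewer than ``min_samples`` matched samples in either condition is an
    error, since density-based MI on a handful of samples is meaningless.

    Returns a ``(ConditionData, ConditionData)`` pair for conditions a, b.
    """
    shared = set(mrna.sample_ids) & set(mirna.sample_ids)
    dropped = (set(mrna.sample_ids) | set(mirna.sample_ids)) - shared
    if dropped:
        logger.info("dropping %d samples not matched across platforms", len(dropped))
    out = []
    for condition in (condition_a, condition_b):
        wanted = {s for s in groups.samples_of(condition)} & shared
        ordered = [s for s in mrna.sample_ids if s in wanted]
        if len(ordered) < min_samples:
            raise ValueError(
                f"condition {condition!r} has {len(ordered)} matched samples; "
                f"need >= {min_samples}"
            )
        logger.info("condition %r: %d matched samples", condition, len(ordered))
        out.append(ConditionData(condition,
                                 mrna.subset_samples(ordered),
                                 mirna.subset_samples(ordered)))
    return tuple(out)
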