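"""Domain containers and plain-text readers/writers.

Every file the pipeline touches is a small UTF-8 text format: two-column TSV
tables for fold changes, interactions and ortholog maps, GMT for gene-set
collections, and a wide TSV for probe-level expression matrices.  All readers
validate and report the offending file and line number; all writer/reader
pairs round-trip bit-exactly ("." decimal point, "\t" separator, one header
row).

Gene-identifier matching is exact and case-sensitive throughout; callers that
need to compare mouse symbols against human orthologs can opt into explicit
uppercase normalization where a function exposes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("wsinet")

NAMESPACES = ("BP", "CC", "pathway")


class FormatError(ValueError):
    """Malformed input file; message carries file path and line number."""


def _data_lines(fh):
    """Yield (lineno, line) pairs, skipping blank and '#' comment lines."""
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield lineno, line



# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class FoldChangeTable:
    """Per-contrast map of gene id -> log2 fold change.

    Gene ids are unique and case-preserved; values are finite reals.
    """

    contrast: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, v in self.entries.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite fold change for gene(s): {bad[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, gene: str) -> float:
        return self.entries[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoldChangeTable):
            return NotImplemented
        return self.contrast == other.contrast and self.entries == other.entries

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def restrict(self, genes: Iterable[str]) -> "FoldChangeTable":
        keep = [g for g in self.entries if g in set(genes)]
        return FoldChangeTable(self.contrast, {g: self.entries[g] for g in keep})

    def to_series(self) -> pd.Series:
        return pd.Series(self.entries, name=self.contrast, dtype=float)


@dataclass
class InteractionSet:
    """Undirected protein-protein interaction edge list.

    Self-loop free and duplicate free; an unordered pair is stored as a
    sorted tuple.
    """

    edges: set[tuple[str, str]] = field(default_factory=set)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop edge ({a}, {b}) not allowed")
        self.edges.add(self._key(a, b))

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self.edges

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}


@dataclass
class GeneSet:
    name: str
    namespace: str
    members: set[str]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(
                f"namespace {self.namespace!r} not one of {NAMESPACES}"
            )
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """Ordered term id -> GeneSet mapping (order preserved for reporting)."""

    terms: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def by_namespace(self, namespace: str) -> "GeneSetCollection":
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}")
        return GeneSetCollection(
            {t: gs for t, gs in self.terms.items() if gs.namespace == namespace}
        )


@dataclass
class OrthologMap:
    """Partial one-to-one mouse gene id -> human gene id relation."""

    pairs: dict[str, str]

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, mouse_id: str) -> str | None:
        return self.pairs.get(mouse_id)

    def translate(self, genes: Iterable[str]) -> dict[str, str]:
        """Map each input id through the relation where defined, identity
        otherwise (human ids pass through untouched)."""
        return {g: self.pairs.get(g, g) for g in genes}


@dataclass
class ExpressionMatrix:
    """Probe-level two-color measurements for one contrast.

    ``ratios`` holds the log2 ratio as scanned, i.e. replicates hybridized in
    the swapped dye orientation carry the opposite sign; ``corrected_ratios``
    re-flips them so every column is on the contrast's reference orientation.
    Foreground/background intensities support the expressed-probe filter.
    """

    contrast: str
    probes: list[str]
    replicates: list[str]
    dye_swap: np.ndarray  # bool, per replicate
    ratios: np.ndarray  # probes x replicates, log2, swap orientation as stored
    foreground: np.ndarray | None = None
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dye_swap = np.asarray(self.dye_swap, dtype=bool)
        self.ratios = np.asarray(self.ratios, dtype=float)
        n, k = self.ratios.shape
        if k < 2:
            raise ValueError("need >= 2 replicates")
        if len(self.probes) != n or len(self.replicates) != k:
            raise ValueError("probe/replicate labels do not match matrix shape")
        if self.dye_swap.shape != (k,):
            raise ValueError("dye_swap must have one flag per replicate")
        if k % 2 == 0 and self.dye_swap.sum() != k // 2:
            raise ValueError("dye-swap flags must be balanced for even replicate counts")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def corrected_ratios(self) -> np.ndarray:
        """Log2 ratios with the dye-swap sign convention undone."""
        sign = np.where(self.dye_swap, -1.0, 1.0)
        return self.ratios * sign


# ---------------------------------------------------------------------------
# Fold-change tables
# ---------------------------------------------------------------------------


def read_fc_table(path: str, contrast: str | None = None) -> FoldChangeTable:
    """Read a two-column (gene id, log2 FC) TSV with one header line.

    The header's second field names the contrast unless one is given.
    Duplicate gene ids and non-numeric values are hard errors naming the
    offender and its line.
    """
    entries: dict[str, float] = {}
    label = contrast
    with open(path, encoding="utf-8") as fh:
        rows = _data_lines(fh)
        try:
            _, header_line = next(rows)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        header = header_line.split("\t")
        label = contrast or (header[1] if len(header) > 1 else "fc")
        for lineno, line in rows:
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            gene, raw = parts
            if gene in entries:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            try:
                value = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {raw!r} for gene {gene!r}"
                ) from None
            entries[gene] = value
    return FoldChangeTable(label, entries)


def write_fc_table(table: FoldChangeTable, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"gene\t{table.contrast}\n")
        for gene, value in table.entries.items():
            fh.write(f"{gene}\t{float(value)!r}\n")


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file: term id, description, then members, tab-separated.

    Term order is preserved.  The description field carries the namespace as
    ``namespace|free text`` (written by :func:`write_gmt`); a bare
    description defaults the namespace to ``BP``.
    """
    terms: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in _data_lines(fh):
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 member"
                )
            term_id, desc = parts[0], parts[1]
            if term_id in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            if "|" in desc:
                namespace, name = desc.split("|", 1)
            else:
                namespace, name = "BP", desc
            if namespace not in NAMESPACES:
                raise FormatError(
                    f"{path}:{lineno}: unknown namespace {namespace!r} for {term_id!r}"
                )
            members = {m for m in parts[2:] if m}
            if not members:
                raise FormatError(f"{path}:{lineno}: term {term_id!r} has no members")
            terms[term_id] = GeneSet(name=name, namespace=namespace, members=members)
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id, gs in collection.terms.items():
            members = "\t".join(sorted(gs.members))
            fh.write(f"{term_id}\t{gs.namespace}|{gs.name}\t{members}\n")


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------


def read_interactions(path: str) -> InteractionSet:
    """Read a two-column interaction TSV (one header line).

    Reversed duplicates collapse onto a single undirected edge; a self-loop
    line is skipped with a warning rather than raising.
    """
    iset = InteractionSet()
    with open(path, encoding="utf-8") as fh:
        rows = _data_lines(fh)
        next(rows, None)  # header
        for lineno, line in rows:
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            a, b = parts
            if a == b:
                logger.warning("%s:%d: skipping self-loop interaction (%s, %s)", path, lineno, a, b)
                continue
            iset.add(a, b)
    return iset


def write_interactions(iset: InteractionSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(iset.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Ortholog maps
# ---------------------------------------------------------------------------


def read_ortholog_map(path: str) -> OrthologMap:
    pairs: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        rows = _data_lines(fh)
        next(rows, None)  # header
        for lineno, line in rows:
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            mouse, human = parts
            if mouse in pairs:
                raise FormatError(
                    f"{path}:{lineno}: mouse id {mouse!r} mapped more than once"
                )
            pairs[mouse] = human
    return OrthologMap(pairs)


def write_ortholog_map(omap: OrthologMap, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mouse\thuman\n")
        for mouse, human in sorted(omap.pairs.items()):
            fh.write(f"{mouse}\t{human}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def write_expression_matrix(matrix: ExpressionMatrix, path: str) -> None:
    """Wide TSV: ratio columns encode the dye-swap flag in their header
    (``ratio:R1:swap`` vs ``ratio:R1:ref``)."""
    cols = ["probe"]
    for j, rep in enumerate(matrix.replicates):
        orient = "swap" if matrix.dye_swap[j] else "ref"
        cols.append(f"ratio:{rep}:{orient}")
    if matrix.foreground is not None:
        cols += [f"fg:{rep}" for rep in matrix.replicates]
        cols += [f"bg:{rep}" for rep in matrix.replicates]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, probe in enumerate(matrix.probes):
            row = [probe] + [repr(float(v)) for v in matrix.ratios[i]]
            if matrix.foreground is not None:
                row += [repr(float(v)) for v in matrix.foreground[i]]
                row += [repr(float(v)) for v in matrix.background[i]]
            fh.write("\t".join(row) + "\n")


def read_expression_matrix(path: str, contrast: str | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"probe": str}, comment="#",
                     float_precision="round_trip")
    ratio_cols = [c for c in df.columns if c.startswith("ratio:")]
    if not ratio_cols:
        raise FormatError(f"{path}: no ratio columns found")
    replicates, dye_swap = [], []
    for c in ratio_cols:
        _, rep, orient = c.split(":")
        if orient not in ("ref", "swap"):
            raise FormatError(f"{path}: bad ratio column header {c!r}")
        replicates.append(rep)
        dye_swap.append(orient == "swap")
    fg_cols = [f"fg:{r}" for r in replicates]
    bg_cols = [f"bg:{r}" for r in replicates]
    has_bg = all(c in df.columns for c in fg_cols + bg_cols)
    return ExpressionMatrix(
        contrast=contrast or "contrast",
        probes=list(df["probe"]),
        replicates=replicates,
        dye_swap=np.array(dye_swap),
        ratios=df[ratio_cols].to_numpy(float),
        foreground=df[fg_cols].to_numpy(float) if has_bg else None,
        background=df[bg_cols].to_numpy(float) if has_bg else None,
    )


def write_tsv(df: pd.DataFrame, path: str, seed: int | None = None) -> None:
    """Write a result table; an optional seed is recorded in a leading
    comment so every output names the randomness that produced it."""
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)
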