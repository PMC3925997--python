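"""Readers and writers for the standard file dialects.

Formats handled here:

* expression matrix — TSV, first column gene IDs, header row sample IDs,
  log-scale normalized intensities;
* ortholog groups — OrthoMCL ``groups.txt`` dialect
  (``GROUP_ID: sp|gene sp|gene ...``) with an optional bit-score side table
  (``geneA<TAB>geneB<TAB>score``);
* transcription-factor lists — one gene ID per line, ``#`` comments;
* GO annotation maps — ``gene<TAB>GO:NNNNNNN`` pairs;
* network edge lists — ``source<TAB>target<TAB>clr_score<TAB>directed{0,1}``.

All readers reject malformed input (naming the offending line) rather than
silently repairing it, and every writer produces files its reader accepts.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "OrthologMap",
    "AnnotationSet",
    "ParseError",
    "read_expression",
    "write_expression",
    "read_ortholog_groups",
    "write_ortholog_groups",
    "read_tf_list",
    "write_tf_list",
    "read_go_map",
    "write_go_map",
    "read_edge_list",
    "write_edge_list",
    "transfer_annotations",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log-scale expression values for one species.

    Gene and sample identifiers are unique and order-preserving; values are
    finite floats (files with missing or non-numeric cells are rejected at
    load time).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class OrthologMap:
    """Cross-species ortholog groups with optional per-pair BLAST bit-scores.

    Genes in the same group from different species are predicted orthologs;
    from the same species, predicted paralogs.  Each (species, gene) belongs
    to at most one group.
    """

    groups: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    bitscore: dict[frozenset[str], float] = field(default_factory=dict)
    _gene_group: dict[tuple[str, str], str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._gene_group:
            for gid, members in self.groups.items():
                for member in members:
                    if member in self._gene_group:
                        raise ValueError(f"gene {member} in two groups")
                    self._gene_group[member] = gid

    def group_of(self, species: str, gene: str) -> str | None:
        return self._gene_group.get((species, gene))

    def orthologs(self, species: str, gene: str, other_species: str) -> set[str]:
        """Genes in *other_species* sharing a group with (species, gene)."""
        gid = self.group_of(species, gene)
        if gid is None:
            return set()
        return {g for sp, g in self.groups[gid] if sp == other_species and sp != species}

    def paralogs(self, species: str, gene: str) -> set[str]:
        gid = self.group_of(species, gene)
        if gid is None:
            return set()
        return {g for sp, g in self.groups[gid] if sp == species and g != gene}

    def get_bitscore(self, gene_a: str, gene_b: str) -> float:
        """Bit-score for an ortholog pair; missing scores rank as -inf."""
        return self.bitscore.get(frozenset((gene_a, gene_b)), float("-inf"))

    def species_genes(self, species: str) -> set[str]:
        return {g for (sp, g) in self._gene_group if sp == species}


@dataclass
class AnnotationSet:
    """TF identifiers and GO annotations for one species."""

    tf_ids: set[str] = field(default_factory=set)
    go_map: dict[str, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# expression TSV


def read_expression(path: str | Path, species: str = "") -> ExpressionMatrix:
    """Read a genes × samples TSV (gene IDs in column 1, sample IDs in header)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        if not sample_ids:
            raise ParseError(f"{path}:1: no sample columns")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(parts)}"
                )
            gid = parts[0]
            if gid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
            seen.add(gid)
            try:
                row = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if not all(np.isfinite(row)):
                raise ParseError(f"{path}:{lineno}: non-finite value")
            gene_ids.append(gid)
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no gene rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float), species=species)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# OrthoMCL groups.txt


def read_ortholog_groups(
    path: str | Path, bitscore_path: str | Path | None = None
) -> OrthologMap:
    """Parse an OrthoMCL-style groups file (``GROUP: sp|gene sp|gene ...``)."""
    path = Path(path)
    groups: dict[str, set[tuple[str, str]]] = {}
    seen: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError(f"{path}:{lineno}: missing ':' group separator")
            gid, _, rest = line.partition(":")
            gid = gid.strip()
            members: set[tuple[str, str]] = set()
            for token in rest.split():
                if "|" not in token:
                    raise ParseError(f"{path}:{lineno}: malformed member token {token!r}")
                sp, _, gene = token.partition("|")
                if not sp or not gene:
                    raise ParseError(f"{path}:{lineno}: malformed member token {token!r}")
                member = (sp, gene)
                if member in seen:
                    raise ParseError(
                        f"{path}:{lineno}: gene {token!r} already in group {seen[member]!r}"
                    )
                seen[member] = gid
                members.add(member)
            groups[gid] = members
    bitscore: dict[frozenset[str], float] = {}
    if bitscore_path is not None:
        with open(bitscore_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"{bitscore_path}:{lineno}: expected 3 fields")
                try:
                    score = float(parts[2])
                except ValueError:
                    raise ParseError(
                        f"{bitscore_path}:{lineno}: non-numeric bit-score"
                    ) from None
                bitscore[frozenset((parts[0], parts[1]))] = score
    return OrthologMap(groups=groups, bitscore=bitscore)


def write_ortholog_groups(
    omap: OrthologMap, path: str | Path, bitscore_path: str | Path | None = None
) -> None:
    with open(path, "w") as fh:
        for gid in sorted(omap.groups):
            members = " ".join(
                f"{sp}|{gene}" for sp, gene in sorted(omap.groups[gid])
            )
            fh.write(f"{gid}: {members}\n")
    if bitscore_path is not None:
        with open(bitscore_path, "w") as fh:
            for pair in sorted(omap.bitscore, key=sorted):
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\t{omap.bitscore[pair]!r}\n")


# ---------------------------------------------------------------------------
# TF lists and GO maps


def read_tf_list(path: str | Path) -> set[str]:
    tfs: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                tfs.add(line)
    return tfs


def write_tf_list(tf_ids: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in sorted(tf_ids):
            fh.write(tf + "\n")


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    path = Path(path)
    go_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            go_map.setdefault(parts[0], set()).add(parts[1])
    return go_map


def write_go_map(go_map: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# network edge lists


def read_edge_list(path: str | Path) -> list[tuple[str, str, float, bool]]:
    """Read ``source<TAB>target<TAB>clr_score<TAB>directed{0,1}`` rows."""
    path = Path(path)
    edges: list[tuple[str, str, float, bool]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("source\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            try:
                score = float(parts[2])
                directed = int(parts[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed edge row") from None
            if directed not in (0, 1):
                raise ParseError(f"{path}:{lineno}: directed flag must be 0 or 1")
            edges.append((parts[0], parts[1], score, bool(directed)))
    return edges


def write_edge_list(
    edges: list[tuple[str, str, float, bool]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tclr_score\tdirected\n")
        for src, dst, score, directed in edges:
            fh.write(f"{src}\t{dst}\t{score!r}\t{int(directed)}\n")


# ---------------------------------------------------------------------------
# annotation transfer


def transfer_annotations(
    go_map: dict[str, set[str]],
    source_species: str,
    target_species: str,
    omap: OrthologMap,
) -> dict[str, set[str]]:
    """Propagate GO terms from an annotated species through ortholog groups.

    A target gene receives the union of the terms of all its orthologs in the
    source species; target genes with no annotated ortholog are absent from
    the result.
    """
    out: dict[str, set[str]] = {}
    for gene, terms in go_map.items():
        if not terms:
            continue
        for target in omap.orthologs(source_species, gene, target_species):
            out.setdefault(target, set()).update(terms)
    return out
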