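"""Core data containers: OTU tables, phylogenies, distance matrices, metadata.

All pipeline stages exchange data through the small set of validated
containers defined here.  The internal orientation for community tables is
samples-as-rows everywhere; distance matrices are square, symmetric and
hollow; trees are rooted with branch lengths on every non-root edge.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "OtuTable",
    "DistanceMatrix",
    "PhyloTree",
    "SampleMetadata",
]


class FormatError(ValueError):
    """An input file or table violates the expected format."""


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OtuTable:
    """A samples x OTUs abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample ids as the index and OTU ids as columns.
        Entries are nonnegative counts or, if ``is_relative`` is set,
        per-sample proportions summing to one.
    is_relative
        Whether rows are proportions rather than counts.
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric entries in OTU table")
        if not np.all(np.isfinite(values)):
            raise FormatError("non-finite entries in OTU table")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at sample {self.data.index[r]!r}, "
                f"OTU {self.data.columns[c]!r}"
            )
        if self.is_relative:
            totals = values.sum(axis=1)
            if not np.allclose(totals, 1.0, atol=1e-9):
                bad = self.data.index[np.abs(totals - 1.0) > 1e-9].tolist()
                raise FormatError(f"relative-abundance rows do not sum to 1: {bad}")

    # -- basic accessors ----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def otu_ids(self) -> list[str]:
        return [str(o) for o in self.data.columns]

    @property
    def counts(self) -> np.ndarray:
        """Abundance matrix, shape (n_samples, n_otus), float copy."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    # -- transforms ---------------------------------------------------------

    def to_relative(self) -> "OtuTable":
        """Divide each row by its total.

        Raises
        ------
        ValueError
            If any sample has zero total abundance (the proportion is
            undefined); the message lists the offending sample ids.
        """
        totals = self.data.sum(axis=1)
        zero = totals[totals == 0].index.tolist()
        if zero:
            raise ValueError(f"zero-total samples, cannot normalize: {zero}")
        return OtuTable(self.data.div(totals, axis=0), is_relative=True)

    def drop_empty_otus(self) -> "OtuTable":
        """Remove OTUs with zero abundance in every sample."""
        keep = self.data.sum(axis=0) > 0
        return OtuTable(self.data.loc[:, keep], is_relative=self.is_relative)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return OtuTable(self.data.loc[list(sample_ids)], is_relative=self.is_relative)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.is_relative == other.is_relative
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.array_equal(self.data.to_numpy(dtype=float),
                               other.data.to_numpy(dtype=float))
        )


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with labelled ids.

    The diagonal must be zero, entries nonnegative, and asymmetry no larger
    than 1e-12 (the matrix is exactly symmetrized on construction).
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate ids in distance matrix")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise FormatError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} ids"
            )
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise FormatError("distance matrix not symmetric within 1e-12")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 0:
            raise FormatError("distance matrix diagonal not zero")
        if (self.values < 0).any():
            raise FormatError("negative distances")
        self.values = (self.values + self.values.T) / 2.0

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy condensed) order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"ids not in distance matrix: {missing}")
        idx = np.array([index[s] for s in ids])
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids),
                            columns=list(self.ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise FormatError("distance matrix rows and columns differ")
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------

class PhyloTree:
    """Rooted phylogeny with branch lengths; tips are OTU ids.

    Wraps a :class:`dendropy.Tree` and caches the patristic (tip-to-tip
    path-length) distance matrix.  Every non-root edge must carry a
    nonnegative branch length; tip labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label if leaf.taxon is not None else None
                  for leaf in tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise FormatError("tree has unlabelled tips")
        if len(set(labels)) != len(labels):
            seen: set[str] = set()
            dups = sorted({lab for lab in labels
                           if lab in seen or seen.add(lab)})
            raise FormatError(f"duplicate tip labels: {dups}")
        root = tree.seed_node
        for edge in tree.preorder_edge_iter():
            if edge.head_node is root:
                continue  # the root edge may legitimately be absent
            if edge.length is None:
                raise FormatError("tree edge without branch length")
            if edge.length < 0:
                raise FormatError("negative branch length")
        self._labels: tuple[str, ...] = tuple(labels)
        self._patristic: DistanceMatrix | None = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                rooting="force-rooted",
            )
        except Exception as exc:  # dendropy raises several error types
            if "Duplicate taxon labels" in str(exc):
                raise FormatError(f"duplicate tip labels: {exc}") from exc
            raise FormatError(f"unparseable newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_path(cls, path) -> "PhyloTree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip() + "\n"

    # -- accessors ----------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    def total_branch_length(self) -> float:
        root = self._tree.seed_node
        return float(sum(e.length for e in self._tree.preorder_edge_iter()
                         if e.head_node is not root and e.length is not None)
                     + (self._tree.seed_node.edge.length or 0.0))

    # -- patristic distances ------------------------------------------------

    def patristic(self) -> DistanceMatrix:
        """Tip-to-tip path-length distance matrix over all tips.

        Computed once by a postorder sweep (children's tip-distance lists are
        merged with an outer sum at each internal node) and cached.
        """
        if self._patristic is None:
            labels = self._labels
            index = {lab: i for i, lab in enumerate(labels)}
            n = len(labels)
            dist = np.zeros((n, n))
            # node -> (tip indices below it, distances from node to those tips)
            below: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            for node in self._tree.postorder_node_iter():
                if node.is_leaf():
                    below[id(node)] = (
                        np.array([index[node.taxon.label]]),
                        np.zeros(1),
                    )
                    continue
                parts = []
                for child in node.child_nodes():
                    idx, d = below.pop(id(child))
                    parts.append((idx, d + child.edge.length))
                for a in range(len(parts)):
                    for b in range(a + 1, len(parts)):
                        ia, da = parts[a]
                        ib, db = parts[b]
                        cross = da[:, None] + db[None, :]
                        dist[np.ix_(ia, ib)] = cross
                        dist[np.ix_(ib, ia)] = cross.T
                idx = np.concatenate([p[0] for p in parts])
                d = np.concatenate([p[1] for p in parts])
                below[id(node)] = (idx, d)
            self._patristic = DistanceMatrix(labels, dist)
        return self._patristic

    def distance(self, a: str, b: str) -> float:
        pd_ = self.patristic()
        ia = pd_.ids.index(a)
        ib = pd_.ids.index(b)
        return float(pd_.values[ia, ib])

    # -- Faith's PD ---------------------------------------------------------

    def faith_pd(self, present: Iterable[str]) -> float:
        """Total branch length of the minimal subtree connecting ``present``
        tips and the root (root path included, QIIME 1 convention)."""
        present = set(present)
        missing = present - set(self._labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if not present:
            return 0.0
        total = 0.0
        root = self._tree.seed_node
        # count an edge if any selected tip lies below it
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                node._pd_hit = node.taxon.label in present
            else:
                node._pd_hit = any(c._pd_hit for c in node.child_nodes())
            if node is not root and node._pd_hit:
                total += node.edge.length
        for node in self._tree.postorder_node_iter():
            del node._pd_hit
        return float(total)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

#: columns with fixed meaning; everything else numeric is an env variable
RESERVED_COLUMNS = ("dsr_level", "group")
PERFORMANCE_COLUMNS = (
    "body_weight_gain", "survival_days", "sIgA", "serum_IgA", "serum_IgG",
)


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample design and environmental variables.

    ``data`` is indexed by sample id and must contain ``dsr_level``
    (integer 1-8).  ``group`` defaults to ``DSR<level>`` when absent.
    ``env_vars`` names the numeric environmental (nutrient) columns; when
    not given, every numeric column that is neither reserved nor a
    performance measurement is treated as environmental.
    """

    data: pd.DataFrame
    env_vars: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in metadata: {dups}")
        if "dsr_level" not in self.data.columns:
            raise FormatError("metadata missing required column 'dsr_level'")
        levels = self.data["dsr_level"]
        if not np.array_equal(levels, levels.astype(int)):
            raise FormatError("dsr_level must be integer")
        self.data = self.data.copy()
        self.data["dsr_level"] = levels.astype(int)
        if ((self.data["dsr_level"] < 1) | (self.data["dsr_level"] > 8)).any():
            raise FormatError("dsr_level out of range [1, 8]")
        if "group" not in self.data.columns:
            self.data["group"] = [f"DSR{v}" for v in self.data["dsr_level"]]
        if self.env_vars is None:
            skip = set(RESERVED_COLUMNS) | set(PERFORMANCE_COLUMNS)
            self.env_vars = tuple(
                c for c in self.data.columns
                if c not in skip and pd.api.types.is_numeric_dtype(self.data[c])
            )
        else:
            self.env_vars = tuple(self.env_vars)
            missing = [v for v in self.env_vars if v not in self.data.columns]
            if missing:
                raise FormatError(f"env variables missing from metadata: {missing}")
        for v in self.env_vars:
            col = self.data[v].to_numpy()
            if not np.issubdtype(col.dtype, np.number) or not np.all(np.isfinite(col)):
                raise FormatError(f"env variable {v!r} has non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def dsr_level(self) -> pd.Series:
        return self.data["dsr_level"]

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    def env(self, var: str) -> pd.Series:
        if var not in self.data.columns:
            raise KeyError(f"unknown metadata variable {var!r}")
        return self.data[var]

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        """Subset and reorder to ``sample_ids`` (which must all be present)."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return SampleMetadata(self.data.loc[list(sample_ids)],
                              env_vars=self.env_vars)
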