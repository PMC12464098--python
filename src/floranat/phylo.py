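"""Phylogenetic relatedness of alien species to the native flora.

Three patristic-distance indices per alien species, following Darwin's
naturalization / pre-adaptation framing:

* ``pd_mean`` — mean distance to all native species (equal contribution of
  the entire native flora),
* ``pd_wmean`` — mean distance weighted by each native's occurrence
  frequency across the 18 Southern African subregions (prevalent natives
  are more likely to interact with the alien),
* ``pd_min`` — distance to the nearest native relative (tip-level signal;
  the closest relative is most likely to share resource requirements,
  mutualists and enemies).

Distances are path sums of branch lengths. They are computed from per-tip
root paths (``d(a, b) = depth(a) + depth(b) - 2 * depth(mrca)``) and, for
the one-against-all-natives case, by a single source-to-all-tips traversal
— the study trees have thousands of tips and only alien x native pairs are
needed, so a full pairwise matrix is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

N_SUBREGIONS = 18  # Southern African subregions used for occurrence counts


def normalize_label(label: str) -> str:
    """Normalize a tip label: underscores for spaces, case-folded.

    Newick exports routinely differ from tabular data in exactly these two
    ways, so matching is done on the normalized form.
    """
    return label.strip().replace(" ", "_").casefold()


@dataclass
class RelatednessRow:
    species_id: str
    pd_mean: float
    pd_wmean: float
    pd_min: float
    nearest_native: str


@dataclass
class PhyloContext:
    """A rooted branch-length tree plus the native/alien tip partition and
    per-native occurrence counts (1..18 subregions)."""

    tree: dendropy.Tree
    natives: frozenset[str]
    aliens: frozenset[str]
    native_occurrence: Mapping[str, int]

    _tips: dict[str, dendropy.Node] = field(init=False, repr=False, default_factory=dict)
    _adjacency: dict = field(init=False, repr=False, default_factory=dict)
    _depth: dict = field(init=False, repr=False, default_factory=dict)
    _order: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.natives = frozenset(normalize_label(x) for x in self.natives)
        self.aliens = frozenset(normalize_label(x) for x in self.aliens)
        self.native_occurrence = {
            normalize_label(k): int(v) for k, v in dict(self.native_occurrence).items()
        }
        if not self.natives:
            raise ValidationError("native species set is empty")
        clash = self.natives & self.aliens
        if clash:
            raise ValidationError(
                f"tips designated both native and alien: {sorted(clash)[:5]}"
            )
        self._index_tree()
        missing = (self.natives | self.aliens) - set(self._tips)
        if missing:
            raise ValidationError(f"labels not found as tree tips: {sorted(missing)[:5]}")
        bad_occ = {
            k: v
            for k, v in self.native_occurrence.items()
            if not (1 <= v <= N_SUBREGIONS)
        }
        if bad_occ:
            raise ValidationError(
                f"occurrence counts outside [1, {N_SUBREGIONS}]: {bad_occ}"
            )

    # -- tree indexing -------------------------------------------------

    def _index_tree(self) -> None:
        tree = self.tree
        root = tree.seed_node
        order = 0
        # preorder pass: depths, parent adjacency, tip lookup
        stack = [(root, 0.0)]
        while stack:
            node, depth = stack.pop()
            self._depth[node] = depth
            self._order[node] = order
            order += 1
            for child in node.child_nodes():
                bl = child.edge.length
                if bl is None:
                    raise ValidationError(
                        "tree has a missing branch length (edge to "
                        f"{child.taxon.label if child.taxon else 'an internal node'})"
                    )
                if bl < 0:
                    raise ValidationError("tree has a negative branch length")
                self._adjacency.setdefault(node, []).append((child, float(bl)))
                self._adjacency.setdefault(child, []).append((node, float(bl)))
                stack.append((child, depth + float(bl)))
            if node.is_leaf():
                if node.taxon is None or node.taxon.label is None:
                    raise ValidationError("tree has an unlabeled tip")
                label = normalize_label(node.taxon.label)
                if label in self._tips:
                    raise ValidationError(f"duplicate tip label {label!r}")
                self._tips[label] = node

    def tip(self, label: str) -> dendropy.Node:
        key = normalize_label(label)
        if key not in self._tips:
            raise ValidationError(f"unknown tip label {label!r}")
        return self._tips[key]

    @classmethod
    def from_files(
        cls,
        tree_path: str | Path,
        occurrence_path: str | Path,
        aliens: Iterable[str] | None = None,
    ) -> "PhyloContext":
        """Build a context from a Newick file and a two-column CSV of
        (native tip label, occurrence count). When ``aliens`` is omitted,
        every tip not listed as native is treated as alien."""
        tree_path = Path(tree_path)
        if not tree_path.exists():
            raise ConfigurationError(f"tree file not found: {tree_path}")
        tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
        occ = pd.read_csv(occurrence_path)
        if occ.shape[1] < 2:
            raise ConfigurationError(
                "occurrence file needs two columns: tip label, count"
            )
        labels = occ.iloc[:, 0].astype(str)
        counts = occ.iloc[:, 1].astype(int)
        native_occurrence = dict(zip(labels, counts))
        natives = set(normalize_label(x) for x in labels)
        if aliens is None:
            all_tips = {
                normalize_label(leaf.taxon.label)
                for leaf in tree.leaf_node_iter()
                if leaf.taxon is not None
            }
            aliens = all_tips - natives
        return cls(
            tree=tree,
            natives=frozenset(natives),
            aliens=frozenset(aliens),
            native_occurrence=native_occurrence,
        )


def _mrca_depth(ctx: PhyloContext, a: dendropy.Node, b: dendropy.Node) -> float:
    # climb the deeper (by preorder index trick: use parents) node first
    seen = set()
    x = a
    while x is not None:
        seen.add(x)
        x = x.parent_node
    x = b
    while x is not None:
        if x in seen:
            return ctx._depth[x]
        x = x.parent_node
    raise ValidationError("tips do not share a root (disconnected tree)")


def patristic_distance(ctx: PhyloContext, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between tips ``a`` and ``b``."""
    na, nb = ctx.tip(a), ctx.tip(b)
    if na is nb:
        return 0.0
    return ctx._depth[na] + ctx._depth[nb] - 2.0 * _mrca_depth(ctx, na, nb)


def _distances_to_natives(ctx: PhyloContext, source: dendropy.Node) -> dict[str, float]:
    """Single-source traversal over the (acyclic) tree graph, collecting the
    path-length to every native tip."""
    native_nodes = {ctx._tips[lab]: lab for lab in ctx.natives}
    out: dict[str, float] = {}
    stack = [(source, None, 0.0)]
    while stack:
        node, prev, dist = stack.pop()
        if node in native_nodes:
            out[native_nodes[node]] = dist
        for nbr, w in ctx._adjacency.get(node, ()):
            if nbr is not prev:
                stack.append((nbr, node, dist + w))
    return out


def compute_relatedness(ctx: PhyloContext, alien: str) -> RelatednessRow:
    """PD indices for one alien species against the whole native flora."""
    key = normalize_label(alien)
    if key not in ctx.aliens:
        raise ValidationError(f"{alien!r} is not a designated alien tip")
    missing_occ = ctx.natives - set(ctx.native_occurrence)
    if missing_occ:
        raise ValidationError(
            f"missing occurrence counts for natives: {sorted(missing_occ)[:5]}"
        )
    dists = _distances_to_natives(ctx, ctx.tip(key))
    n = len(ctx.natives)
    total = sum(dists.values())
    wsum = sum(ctx.native_occurrence[lab] * d for lab, d in dists.items())
    wtot = sum(ctx.native_occurrence[lab] for lab in dists)
    # deterministic tie-break on label for the nearest native
    nearest = min(dists.items(), key=lambda kv: (kv[1], kv[0]))
    return RelatednessRow(
        species_id=key,
        pd_mean=total / n,
        pd_wmean=wsum / wtot,
        pd_min=nearest[1],
        nearest_native=nearest[0],
    )


def relatedness_table(ctx: PhyloContext) -> pd.DataFrame:
    """One row per alien species, joinable to the species table on
    ``species_id``."""
    rows = [compute_relatedness(ctx, alien) for alien in sorted(ctx.aliens)]
    return pd.DataFrame(
        {
            "species_id": [r.species_id for r in rows],
            "pd_mean": [r.pd_mean for r in rows],
            "pd_wmean": [r.pd_wmean for r in rows],
            "pd_min": [r.pd_min for r in rows],
            "nearest_native": [r.nearest_native for r in rows],
        }
    )
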