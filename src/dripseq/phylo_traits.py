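"""Parsimony mapping of gene losses on a species tree.

Gene presence/absence calls across species are mapped onto a rooted
species tree under a Dollo model: the gene arose once (present at the
root) and can only be lost. The minimal-loss reconstruction places one
loss on each edge leading to a maximal all-absent subtree. Fitch small
parsimony (gains and losses both allowed) is provided as a cross-check
— its change count can only be lower or equal.

A curated fixture ships with the package: a representative rooted tree
of 24 Ascomycota/Basidiomycota taxa and the presence/absence pattern of
the EJC core components (MAGO, Y14) and peripheral factors, transcribed
at clade level from published homology screens. The fixture is curated
data, not an inference made by this package.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import IO, Iterable, Mapping

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

PRESENT = "+"
ABSENT = "-"


def parse_newick(source: str | IO[str]) -> dendropy.Tree:
    """Parse a rooted newick tree.

    Raises on duplicate tip labels and on trees whose root has more
    than two children (supply a rooted tree).
    """
    if hasattr(source, "read"):
        data = source.read()
    elif "(" in source:
        data = source
    else:
        with open(source) as fh:
            data = fh.read()
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(data=data, schema="newick",
                                 suppress_internal_node_taxa=True)
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {t for t in labels if labels.count(t) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    if len(tree.seed_node.child_nodes()) > 2:
        raise ValueError(
            "tree root has more than two children; supply a rooted tree"
        )
    tree.is_rooted = True
    return tree


def _tip_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(
        leaf.taxon.label.replace(" ", "_") for leaf in node.leaf_iter()
    )


def dollo_min_losses(
    tree: dendropy.Tree, presence: Mapping[str, bool] | Iterable[str]
) -> tuple[int, set[frozenset[str]]]:
    """Minimal loss count and loss edges under a Dollo model.

    ``presence`` is either a mapping tip -> bool or the set of tips
    carrying the gene; tips absent from it are treated as lacking the
    gene. Loss edges are returned as the tip sets of the maximal
    all-absent subtrees they subtend. A character absent from every tip
    is reported as a single loss on the root edge (with a warning).
    """
    if isinstance(presence, Mapping):
        present_tips = {t.replace(" ", "_") for t, v in presence.items() if v}
    else:
        present_tips = {t.replace(" ", "_") for t in presence}
    tips = _tip_labels(tree.seed_node)
    unknown = present_tips - tips
    if unknown:
        raise ValueError(f"presence calls for unknown tips: {sorted(unknown)}")

    if not present_tips:
        logger.warning("character absent from all tips; one loss on root edge")
        return 1, {tips}

    all_absent: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label.replace(" ", "_")
            all_absent[node] = label not in present_tips
        else:
            all_absent[node] = all(all_absent[c] for c in node.child_nodes())

    loss_edges: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if all_absent[node] and (parent is None or not all_absent[parent]):
            loss_edges.add(_tip_labels(node))
    return len(loss_edges), loss_edges


def fitch_min_changes(
    tree: dendropy.Tree, presence: Mapping[str, bool] | Iterable[str]
) -> int:
    """Fitch small-parsimony count of state changes for a binary character."""
    if isinstance(presence, Mapping):
        present_tips = {t.replace(" ", "_") for t, v in presence.items() if v}
    else:
        present_tips = {t.replace(" ", "_") for t in presence}
    changes = 0
    state: dict[dendropy.Node, frozenset[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label.replace(" ", "_")
            state[node] = frozenset({1 if label in present_tips else 0})
        else:
            sets = [state[c] for c in node.child_nodes()]
            acc = sets[0]
            for s in sets[1:]:
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    changes += 1
            state[node] = acc
    return changes


def load_traits(source: str | IO[str]) -> pd.DataFrame:
    """Read a species x factors trait table (TSV, +/- calls).

    The first column is the species name; any non-factor annotation
    columns (e.g. family, clade membership) are kept as-is.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    return df.set_index(df.columns[0])


def package_cooccurrence(
    traits: pd.DataFrame,
    factor_set: Iterable[str],
    species_filter: Iterable[str] | pd.Series | None = None,
) -> tuple[int, pd.DataFrame]:
    """Count species carrying every factor in ``factor_set``.

    ``species_filter`` restricts to a clade: either an explicit species
    list or a boolean Series over the trait rows. Returns the count and
    the pairwise co-occurrence table of the requested factors (within
    the same filter).
    """
    factors = list(factor_set)
    unknown = [f for f in factors if f not in traits.columns]
    if unknown:
        raise KeyError(f"unknown factors: {unknown}")
    sub = traits
    if species_filter is not None:
        if isinstance(species_filter, pd.Series):
            sub = traits.loc[species_filter.reindex(traits.index).fillna(False)]
        else:
            sub = traits.loc[[s for s in traits.index if s in set(species_filter)]]
    present = sub[factors] == PRESENT
    count = int(present.all(axis=1).sum())
    pairwise = pd.DataFrame(
        present.to_numpy().T.astype(int) @ present.to_numpy().astype(int),
        index=factors, columns=factors,
    )
    return count, pairwise


def load_ejc_fixture() -> tuple[dendropy.Tree, pd.DataFrame]:
    """The packaged curated tree + trait table for the EJC factors."""
    import io

    pkg = resources.files("dripseq") / "data"
    tree = parse_newick((pkg / "ejc_species_tree.nwk").read_text())
    traits = load_traits(io.StringIO((pkg / "ejc_traits.tsv").read_text()))
    return tree, traits


def saccharomycotina_filter(traits: pd.DataFrame) -> pd.Series:
    """Boolean mask over the trait rows for Saccharomycotina species."""
    if "saccharomycotina" not in traits.columns:
        raise KeyError("trait table has no 'saccharomycotina' column")
    return traits["saccharomycotina"] == "yes"
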