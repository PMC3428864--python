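"""Pigeonhole-principle phylogeny of subclones.

Two sets of mutations each present in more than 50% of tumor cells cannot
occupy disjoint subsets of cells — some cell carries both — so the two
events are collinear on the phylogenetic tree; and whenever the fractions
sum to more than 1, the event with the strictly larger fraction must be
ancestral. Combining these pigeonhole constraints with phasing-derived
collinearity/exclusivity gives a partial order that a greedy nesting by
descending cell fraction turns into a clone tree. Placements not forced by
any constraint stay attached at the shallowest consistent point and are
flagged ambiguous rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "CloneNode",
    "Constraint",
    "TreeConflictError",
    "pigeonhole_constraints",
    "build_tree",
    "check_tree",
]

COLLINEAR = "collinear_A_first"
EXCLUSIVE = "exclusive"

EPSILON = 0.02  # tolerance on child-fraction sums (estimates are noisy)


class TreeConflictError(ValueError):
    """Raised when the supplied constraints cannot all hold on one tree."""


@dataclass
class Constraint:
    """A pairwise relation between two events/clusters.

    ``relation`` is ``collinear_A_first`` (A ancestral to B) or
    ``exclusive`` (A and B on different branches). A collinear constraint
    with unknown order (equal fractions) carries ``ordered=False``.
    """

    a: str
    b: str
    relation: str
    ordered: bool = True

    def __post_init__(self) -> None:
        if self.relation not in (COLLINEAR, EXCLUSIVE):
            raise ValueError(f"unknown relation {self.relation!r}")


@dataclass
class CloneNode:
    """A node of the clone tree: a lineage with its cell fraction."""

    label: str
    cell_fraction: float
    n_mutations: int = 0
    cn_events: list[str] = field(default_factory=list)
    children: list["CloneNode"] = field(default_factory=list)
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.cell_fraction <= 1.0 + 1e-9):
            raise ValueError(
                f"cell fraction must be in (0, 1], got {self.cell_fraction}"
            )

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def find(self, label: str) -> "CloneNode | None":
        for node in self.walk():
            if node.label == label:
                return node
        return None

    def is_ancestor_of(self, label: str) -> bool:
        return any(c.find(label) is not None for c in self.children)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "cell_fraction": self.cell_fraction,
            "n_mutations": self.n_mutations,
            "cn_events": list(self.cn_events),
            "ambiguous": self.ambiguous,
            "children": [c.to_dict() for c in self.children],
        }


def pigeonhole_constraints(
    items: Sequence[tuple[str, float]],
) -> list[Constraint]:
    """Collinearity constraints forced by cell fractions alone.

    For every pair of items whose fractions sum to more than 1, no
    apportioning into disjoint cell subsets exists, so the pair is
    collinear; the strictly larger fraction is ancestral. Ties produce a
    collinear constraint with ``ordered=False``.
    """
    out: list[Constraint] = []
    for i, (la, fa) in enumerate(items):
        for lb, fb in items[i + 1 :]:
            if fa + fb <= 1.0 + 1e-12:
                continue
            if fa > fb:
                out.append(Constraint(la, lb, COLLINEAR))
            elif fb > fa:
                out.append(Constraint(lb, la, COLLINEAR))
            else:
                out.append(Constraint(la, lb, COLLINEAR, ordered=False))
    return out


def build_tree(
    clusters: Sequence[tuple[str, float] | tuple[str, float, int]],
    cn_events: Sequence[tuple[str, float]] = (),
    constraints: Sequence[Constraint] = (),
    epsilon: float = EPSILON,
) -> CloneNode:
    """Assemble the clone tree from fractions and pairwise constraints.

    ``clusters`` are (label, cell fraction[, n_mutations]) tuples;
    ``cn_events`` are (label, cell fraction) copy-number events placed as
    tree nodes of their own. ``constraints`` adds phasing-derived
    relations on top of the pigeonhole constraints, which are always
    derived internally from the fractions.

    Items are nested greedily by descending fraction: each item attaches
    under the deepest node that is forced to be its ancestor (the forced
    ancestors always form a chain), or under the root when nothing forces
    it deeper. Exclusive constraints are verified — an exclusive pair
    whose fractions force collinearity raises :class:`TreeConflictError`.
    Items that could consistently nest under some non-forced node are
    flagged ambiguous.
    """
    entries: list[dict] = []
    for item in clusters:
        label, frac = item[0], item[1]
        n_mut = item[2] if len(item) > 2 else 0
        entries.append({"label": label, "fraction": float(frac), "n_mut": int(n_mut), "cn": False})
    for label, frac in cn_events:
        entries.append({"label": label, "fraction": float(frac), "n_mut": 0, "cn": True})
    if not entries:
        raise ValueError("nothing to build a tree from")
    labels = [e["label"] for e in entries]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    frac_of = {e["label"]: e["fraction"] for e in entries}

    auto = pigeonhole_constraints([(e["label"], e["fraction"]) for e in entries])
    all_constraints = auto + list(constraints)

    exclusive_pairs = {
        frozenset((c.a, c.b)) for c in all_constraints if c.relation == EXCLUSIVE
    }
    # consistency: exclusivity contradicts a fraction sum > 1
    for pair in exclusive_pairs:
        a, b = tuple(pair)
        if frac_of[a] + frac_of[b] > 1.0 + epsilon:
            raise TreeConflictError(
                f"constraint conflict: {a} and {b} are marked exclusive but "
                f"their fractions sum to {frac_of[a] + frac_of[b]:.3f} > 1"
            )
    ancestor_of: dict[str, set[str]] = {e["label"]: set() for e in entries}
    unordered: set[frozenset] = set()
    for c in all_constraints:
        if c.relation != COLLINEAR:
            continue
        if c.ordered:
            ancestor_of[c.b].add(c.a)
        else:
            unordered.add(frozenset((c.a, c.b)))

    entries.sort(key=lambda e: -e["fraction"])

    # the root is an explicit fully clonal item, or an implicit MRCA node
    first = entries[0]
    if abs(first["fraction"] - 1.0) <= epsilon:
        root = _make_node(first)
        rest = entries[1:]
    else:
        root = CloneNode(label="MRCA", cell_fraction=1.0)
        rest = entries

    placed = {root.label: root}
    for e in rest:
        label = e["label"]
        forced = [placed[a] for a in ancestor_of[label] if a in placed]
        # forced ancestors form a chain; the deepest is the smallest fraction
        parent = root
        for node in sorted(forced, key=lambda n: -n.cell_fraction):
            if parent.find(node.label) is None:
                raise TreeConflictError(
                    f"forced ancestors of {label} do not form a chain"
                )
            parent = node
        for other in exclusive_pairs:
            if label in other:
                partner = next(iter(other - {label}))
                if parent.label == partner or (
                    partner in placed and placed[partner].find(parent.label)
                ):
                    raise TreeConflictError(
                        f"{label} is exclusive with {partner} but forced beneath it"
                    )
        node = _make_node(e)
        # ambiguity: a non-forced placed node (other than the chosen parent's
        # chain) could also host this item without violating anything
        node.ambiguous = _has_alternative_parent(
            root, node, parent, exclusive_pairs, epsilon
        ) or any(label in pair for pair in unordered)
        parent.children.append(node)
        placed[label] = node
        child_sum = sum(c.cell_fraction for c in parent.children)
        if child_sum > parent.cell_fraction + epsilon:
            raise TreeConflictError(
                f"children of {parent.label} sum to {child_sum:.3f} > "
                f"{parent.cell_fraction:.3f} + {epsilon}"
            )
    check_tree(root, all_constraints, epsilon=epsilon)
    return root


def _make_node(entry: dict) -> CloneNode:
    node = CloneNode(
        label=entry["label"],
        cell_fraction=entry["fraction"],
        n_mutations=entry["n_mut"],
    )
    if entry.get("cn"):
        node.cn_events.append(entry["label"])
    return node


def _has_alternative_parent(
    root: CloneNode,
    node: CloneNode,
    parent: CloneNode,
    exclusive_pairs: set[frozenset],
    epsilon: float,
) -> bool:
    chain = set()
    cursor = root
    while cursor is not None:
        chain.add(cursor.label)
        cursor = next((c for c in cursor.children if c.find(parent.label)), None)
        if cursor is not None and cursor.label == parent.label:
            chain.add(cursor.label)
            break
    for cand in root.walk():
        if cand.label in chain or cand.label == node.label:
            continue
        if frozenset((cand.label, node.label)) in exclusive_pairs:
            continue
        room = cand.cell_fraction - sum(c.cell_fraction for c in cand.children)
        if node.cell_fraction <= room + epsilon and cand.cell_fraction >= node.cell_fraction:
            return True
    return False


def check_tree(
    root: CloneNode, constraints: Sequence[Constraint], epsilon: float = EPSILON
) -> None:
    """Verify every constraint and the fraction nesting rule; raise on failure."""
    for node in root.walk():
        child_sum = sum(c.cell_fraction for c in node.children)
        if child_sum > node.cell_fraction + epsilon:
            raise TreeConflictError(
                f"children of {node.label} exceed its fraction: "
                f"{child_sum:.3f} > {node.cell_fraction:.3f}"
            )
        for c in node.children:
            if c.cell_fraction > node.cell_fraction + 1e-9:
                raise TreeConflictError(
                    f"child {c.label} larger than parent {node.label}"
                )
    for c in constraints:
        na, nb = root.find(c.a), root.find(c.b)
        if na is None or nb is None:
            continue
        if c.relation == COLLINEAR and c.ordered:
            if na.find(c.b) is None:
                raise TreeConflictError(f"collinear constraint {c.a}->{c.b} violated")
        elif c.relation == EXCLUSIVE:
            if na.find(c.b) is not None or nb.find(c.a) is not None:
                raise TreeConflictError(f"exclusive constraint {c.a}|{c.b} violated")
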