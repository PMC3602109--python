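"""Brooks Parsimony Analysis coding (original proposition).

Additive binary coding expands a species presence matrix with one extra
binary character per internal node ("hypothetical ancestor") of the taxon
cladogram: an ancestor is scored present in an area iff any of its
descendant species occurs there (association by descent, inclusive OR).
No area duplication or assumption-1/2 reinterpretation is applied.

The inverse operation — recovering a taxon cladogram from a coded matrix —
is also provided, both as a validation utility (additive binary coding is
just a matrix representation of the tree) and to derive a machine-readable
topology from a published coded matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import dendropy

from .matrix import PresenceMatrix

__all__ = ["TaxonCladogram", "CodingError", "bpa_code", "infer_cladogram_from_coding"]


class CodingError(ValueError):
    pass


@dataclass
class TaxonCladogram:
    """Rooted species cladogram with labelled hypothetical ancestors."""

    tree: dendropy.Tree
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_newick(cls, newick: str) -> "TaxonCladogram":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        return cls(tree=tree)

    @property
    def terminals(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def ancestors(self) -> list[tuple[str, frozenset[str]]]:
        """(label, descendant terminal set) per internal node, in a stable
        order: by label when all internal nodes are labelled (natural sort
        on any trailing integer), else postorder with generated labels."""
        items = []
        for i, node in enumerate(self.tree.postorder_internal_node_iter(), start=1):
            label = node.label or f"anc{i}"
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            items.append((label, clade))
        if all(n.label for n in self.tree.postorder_internal_node_iter()):
            items.sort(key=_natural_key)
        return items

    def clusters(self) -> set[frozenset[str]]:
        return {clade for _, clade in self.ancestors()}

    def validate(self) -> None:
        labels = self.terminals
        if len(labels) != len(set(labels)):
            raise CodingError("duplicate terminal labels")
        anc = [lab for lab, _ in self.ancestors()]
        if len(anc) != len(set(anc)):
            raise CodingError("duplicate ancestor labels")
        for node in self.tree.postorder_internal_node_iter():
            if len(node.child_nodes()) < 2 and node is not self.tree.seed_node:
                raise CodingError("internal node with a single child")

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _natural_key(item):
    label = item[0]
    digits = "".join(ch for ch in label if ch.isdigit())
    return (label.rstrip("0123456789"), int(digits) if digits else 0)


def bpa_code(tree: TaxonCladogram, matrix: PresenceMatrix) -> PresenceMatrix:
    """Append one ancestor column per internal node of ``tree``.

    The matrix's characters must equal the tree's terminals exactly; a
    mismatch raises, listing the symmetric difference — subset the matrix
    (or the tree) first, as when species are absent from the phylogeny.
    """
    tree.validate()
    terms = set(tree.terminals)
    chars = set(matrix.characters)
    if terms != chars:
        raise CodingError(
            "tree terminals and matrix characters differ: "
            f"{sorted(terms.symmetric_difference(chars))}"
        )
    df = matrix.data.copy()
    for label, clade in tree.ancestors():
        if label in df.columns:
            raise CodingError(f"ancestor label {label!r} collides with a character")
        df[label] = df[list(clade)].max(axis=1)
    return PresenceMatrix(df, outgroup=matrix.outgroup)


# ---------------------------------------------------------------------------
# inverse: coded matrix -> cladogram
# ---------------------------------------------------------------------------

def infer_cladogram_from_coding(coded: PresenceMatrix, n_species: int) -> TaxonCladogram:
    """Recover a binary taxon cladogram whose additive binary coding
    reproduces the ancestor block of ``coded``.

    The first ``n_species`` characters are the species columns; the rest
    are ancestor columns.  Requires a fully resolved coding (ancestors =
    species - 1).  Raises ``CodingError`` naming the first inconsistent
    ancestor column if no consistent tree exists; ancestor columns shared
    by more than one ancestor are reported in ``warnings`` (the topology
    is then one consistent resolution).
    """
    chars = coded.characters
    species = chars[:n_species]
    anc_labels = chars[n_species:]
    if len(anc_labels) != n_species - 1:
        raise CodingError(
            f"need exactly {n_species - 1} ancestor columns for a fully "
            f"resolved cladogram of {n_species} species; got {len(anc_labels)}"
        )
    vals = coded.data
    sp_vec = {s: _colmask(vals[s]) for s in species}
    anc_vec = {a: _colmask(vals[a]) for a in anc_labels}

    warnings = []
    seen: dict[int, str] = {}
    for a, v in anc_vec.items():
        if v in seen:
            warnings.append(f"ancestor columns {seen[v]} and {a} are identical")
        else:
            seen[v] = a

    full = 0
    for v in sp_vec.values():
        full |= v
    if full not in set(anc_vec.values()):
        raise CodingError(
            "no ancestor column equals the union of all species columns "
            "(no root candidate)"
        )

    # Bottom-up agglomeration with backtracking: repeatedly merge two
    # current units whose OR equals an unused ancestor column.  Choices
    # that differ only in which of several identical-vector units or
    # identical-column ancestors is picked are equivalent and deduplicated.
    nwk = _agglomerate(species, sp_vec, anc_labels, anc_vec, full)
    if nwk is None:
        bad = _first_inconsistent(anc_labels, anc_vec, sp_vec, species)
        raise CodingError(
            f"no consistent cladogram; first problematic ancestor column: {bad}"
        )
    tree = TaxonCladogram.from_newick(nwk + ";")
    tree.warnings = warnings
    check = bpa_code(tree, coded.subset_characters(species))
    anc_df = coded.data[anc_labels]
    if not check.data[anc_labels].equals(anc_df) and not _same_columns_up_to_labels(
        check, coded, anc_labels
    ):
        raise CodingError("internal check failed: inferred tree does not reproduce coding")
    return tree


def _agglomerate(species, sp_vec, anc_labels, anc_vec, full):
    units = [(sp_vec[s], s) for s in species]  # (vector, newick)
    dead: set = set()  # states proven fruitless (merge order is immaterial)

    def step(units, unused: tuple[str, ...]):
        if len(units) == 1:
            return units[0][1] if not unused else None
        state = (
            tuple(sorted(v for v, _ in units)),
            tuple(sorted(anc_vec[a] for a in unused)),
        )
        if state in dead:
            return None
        by_col: dict[int, str] = {}
        for a in unused:
            by_col.setdefault(anc_vec[a], a)  # identical columns: first only
        tried = set()
        n = len(units)
        for i in range(n):
            vi, ni = units[i]
            for j in range(i + 1, n):
                vj, nj = units[j]
                v = vi | vj
                a = by_col.get(v)
                if a is None:
                    continue
                key = (min(vi, vj), max(vi, vj), v)
                if key in tried:
                    continue
                tried.add(key)
                merged = (v, f"({ni},{nj}){a}")
                rest = [units[k] for k in range(n) if k != i and k != j]
                res = step(rest + [merged], tuple(x for x in unused if x != a))
                if res is not None:
                    return res
        dead.add(state)
        return None

    return step(units, tuple(anc_labels))


def _same_columns_up_to_labels(check, coded, anc_labels) -> bool:
    got = {lab: tuple(check.data[lab]) for lab in anc_labels}
    want = {lab: tuple(coded.data[lab]) for lab in anc_labels}
    return sorted(got.values()) == sorted(want.values())


def _colmask(col) -> int:
    v = 0
    for i, x in enumerate(col):
        if x:
            v |= 1 << i
    return v


def _try_partition(items, vec_left, vec_right, sp_vec, or_of):
    left, right, ambiguous = [], [], []
    for s in items:
        v = sp_vec[s]
        in_l = v & ~vec_left == 0
        in_r = v & ~vec_right == 0
        if in_l and in_r:
            ambiguous.append(s)
        elif in_l:
            left.append(s)
        elif in_r:
            right.append(s)
        else:
            return None
    if len(ambiguous) > 12:
        return None
    for pick in range(1 << len(ambiguous)):
        L = list(left) + [s for j, s in enumerate(ambiguous) if pick >> j & 1]
        R = list(right) + [s for j, s in enumerate(ambiguous) if not pick >> j & 1]
        if L and R and or_of(tuple(L)) == vec_left and or_of(tuple(R)) == vec_right:
            return tuple(L), tuple(R)
    return None


def _first_inconsistent(anc_labels, anc_vec, sp_vec, species):
    for a in anc_labels:
        members = [s for s in species if sp_vec[s] & ~anc_vec[a] == 0]
        if or_of := _or(sp_vec, members):
            if or_of != anc_vec[a]:
                return a
    return anc_labels[0] if anc_labels else "<none>"


def _or(sp_vec, members) -> int:
    v = 0
    for s in members:
        v |= sp_vec[s]
    return v
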