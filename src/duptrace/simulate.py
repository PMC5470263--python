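"""Forward simulator of a two-lineage gene family evolving along a species tree.

The model: a single ancestral gene is duplicated at the root of the species
tree into paralog lineages A and B. A fixed set of diagnostic columns
receives distinct founder variants per lineage — the in-silico analog of a
lineage-specific sequence signature. Both copies then descend every branch
of an ultrametric species tree, accumulating Jukes–Cantor substitutions and
intergenic gene-conversion events that copy a short tract from the
conspecific paralog, homogenizing the copies. Each extant species may lose
one copy (dropout). Because every event is logged, the ground truth —
lineage labels, true diagnostic columns, the event log — is exact.

All randomness flows through one numpy Generator in a fixed order:
pre-order over branches, substitutions before conversions on each branch,
copy A before copy B, dropout draws last in leaf order. Identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .io import (
    Alignment,
    DataError,
    GroupMap,
    SignatureSite,
    SignatureTable,
    read_newick,
    write_newick,
)

_BASES = np.array(["A", "C", "G", "T"], dtype="<U1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SimConfig:
    """Study conditions for one simulated gene family.

    Parameters
    ----------
    n_species:
        Extant species on the tree (>= 2).
    seq_len:
        Alignment columns.
    k_diag:
        Number of diagnostic columns carrying lineage-specific founder
        variants.
    sub_rate:
        Substitutions per site per unit branch length.
    conv_rate:
        Expected gene-conversion events per gene copy per unit branch
        length.
    tract_mean:
        Mean conversion tract length, geometric distribution (columns).
    dropout_p:
        Per-species probability of losing one of the two copies.
    tree_height:
        Root-to-tip depth of the ultrametric species tree.
    seed:
        RNG seed; the only source of randomness.
    diag_span:
        Width of the window holding the diagnostic columns. ``None``
        (default) places them as one contiguous block of ``k_diag``
        columns, mirroring a signature concentrated in a short stretch of
        one exon; a larger span scatters them within a window of that
        width.
    erode_by_substitution:
        When False (default) substitutions at diagnostic columns are
        rejected and resampled, so gene conversion is the only force
        eroding the signature. True lifts the protection.
    """

    n_species: int = 20
    seq_len: int = 300
    k_diag: int = 16
    sub_rate: float = 0.05
    conv_rate: float = 0.0
    tract_mean: float = 50.0
    dropout_p: float = 0.0
    tree_height: float = 1.0
    seed: int = 0
    diag_span: int | None = None
    erode_by_substitution: bool = False

    def validate(self) -> None:
        if self.n_species < 2:
            raise DataError("n_species must be >= 2")
        if self.seq_len < 1:
            raise DataError("seq_len must be >= 1")
        if not (0 <= self.k_diag <= self.seq_len):
            raise DataError("k_diag must satisfy 0 <= k_diag <= seq_len")
        for name in ("sub_rate", "conv_rate", "tree_height"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.tract_mean < 1:
            raise DataError("tract_mean must be >= 1")
        if not (0.0 <= self.dropout_p <= 1.0):
            raise DataError("dropout_p must be in [0, 1]")
        span = self.diag_span if self.diag_span is not None else self.k_diag
        if span < self.k_diag or span > self.seq_len:
            raise DataError("diag_span must satisfy k_diag <= diag_span <= seq_len")


@dataclass(frozen=True)
class ConversionEvent:
    """One gene-conversion event: tract [start, end) copied donor→recipient."""

    branch: str  # label of the branch's child node
    donor: str  # "A" or "B"
    recipient: str
    start: int  # 0-based half-open tract
    end: int


@dataclass(frozen=True)
class Substitution:
    branch: str
    copy: str  # "A" or "B"
    column: int  # 0-based
    from_base: str
    to_base: str


@dataclass
class SimTruth:
    """Ground truth of one simulated family."""

    lineage: dict[str, str]  # seq id -> "A" | "B"
    species_of: dict[str, str]  # seq id -> species label
    diagnostic_columns0: list[int]  # 0-based, ascending
    variants_a: list[str]
    variants_b: list[str]
    events: list[ConversionEvent]
    substitutions: list[Substitution]
    founder_a: str
    founder_b: str
    tree_newick: str
    dropped: dict[str, str]  # species -> lineage lost

    @property
    def diagnostic_columns(self) -> list[int]:
        """1-based diagnostic columns."""
        return [c + 1 for c in self.diagnostic_columns0]

    def to_json(self, path: str | Path, seed: int | None = None) -> None:
        payload = {
            "tool": "duptrace",
            "seed": seed,
            "lineage": self.lineage,
            "species_of": self.species_of,
            "diagnostic_columns": self.diagnostic_columns,  # 1-based
            "variants_a": self.variants_a,
            "variants_b": self.variants_b,
            "founder_a": self.founder_a,
            "founder_b": self.founder_b,
            "tree_newick": self.tree_newick,
            "dropped": self.dropped,
            # events reported 1-based inclusive, matching every other report
            "events": [
                {
                    "branch": e.branch,
                    "donor": e.donor,
                    "recipient": e.recipient,
                    "start": e.start + 1,
                    "end": e.end,
                }
                for e in self.events
            ],
            "substitutions": [
                {
                    "branch": s.branch,
                    "copy": s.copy,
                    "column": s.column + 1,
                    "from": s.from_base,
                    "to": s.to_base,
                }
                for s in self.substitutions
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Species tree

def _random_join_tree(n_species: int, rng: np.random.Generator, height: float) -> dendropy.Tree:
    """Ultrametric tree by random pairwise joins with exponential waits."""
    labels = [f"sp{i + 1:02d}" for i in range(n_species)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    depth = {}
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
        depth[id(nd)] = 0.0
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - depth[id(a)]
        b.edge.length = t - depth[id(b)]
        depth[id(parent)] = t
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)] + [parent]
    root = nodes[0]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    # rescale so every root-to-tip path equals `height`
    total = depth[id(root)]
    if total > 0 and height > 0:
        scale = height / total
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    elif height == 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = 0.0
    _label_internal(tree)
    return tree


def _label_internal(tree: dendropy.Tree) -> None:
    k = 0
    for nd in tree.preorder_node_iter():
        if nd.taxon is None and nd.label is None:
            nd.label = f"n{k}"
            k += 1


def simulate_species_tree(
    n_species: int, seed: int, tree_height: float = 1.0
) -> dendropy.Tree:
    """A random ultrametric species tree with leaves sp01..spNN."""
    if n_species < 2:
        raise DataError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    return _random_join_tree(n_species, rng, tree_height)


# ---------------------------------------------------------------------------
# Sequence evolution

def apply_conversion(
    donor: np.ndarray, recipient: np.ndarray, start: int, end: int
) -> np.ndarray:
    """Copy donor[start:end) onto a copy of recipient; donor untouched."""
    seq_len = len(recipient)
    if not (0 <= start < end <= seq_len):
        raise DataError(
            f"conversion tract [{start},{end}) out of bounds for length {seq_len}"
        )
    out = recipient.copy()
    out[start:end] = donor[start:end]
    return out


def _mutate(
    seq: np.ndarray,
    n_sub: int,
    rng: np.random.Generator,
    protected: set[int],
    branch: str,
    copy: str,
    log: list[Substitution],
) -> np.ndarray:
    seq = seq.copy()
    seq_len = len(seq)
    for _ in range(n_sub):
        pos = int(rng.integers(seq_len))
        while pos in protected:
            pos = int(rng.integers(seq_len))
        old = seq[pos]
        # uniform among the three other bases
        choices = [b for b in range(4) if b != old]
        new = choices[int(rng.integers(3))]
        seq[pos] = new
        log.append(
            Substitution(branch, copy, pos, str(_BASES[old]), str(_BASES[new]))
        )
    return seq


def _branch_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def simulate_family(
    cfg: SimConfig,
) -> tuple[Alignment, GroupMap, SignatureTable, SimTruth]:
    """Simulate one gene family; returns alignment, labels, true signature, truth.

    The duplication sits at the species-tree root: lineages A and B are the
    two copies every species inherits. Substitutions are Poisson with mean
    ``sub_rate * branch_length * seq_len`` per copy per branch; conversion
    events are Poisson with mean ``conv_rate * branch_length`` per copy per
    branch, each copying a geometric tract (mean ``tract_mean``) between the
    conspecific copies in a uniformly chosen direction.
    """
    cfg.validate()
    if cfg.k_diag < 1:
        raise DataError("simulate_family needs k_diag >= 1")
    rng = np.random.default_rng(cfg.seed)
    tree = _random_join_tree(cfg.n_species, rng, cfg.tree_height)

    seq_len, k = cfg.seq_len, cfg.k_diag
    founder = rng.integers(4, size=seq_len)

    span = cfg.diag_span if cfg.diag_span is not None else k
    start = int(rng.integers(seq_len - span + 1))
    if span == k:
        diag = np.arange(start, start + k)
    else:
        diag = start + np.sort(rng.choice(span, size=k, replace=False))
    diag_set = set(int(c) for c in diag)

    founder_a = founder.copy()
    founder_b = founder.copy()
    variants_a, variants_b = [], []
    for c in diag:
        a = int(founder[c])
        b_choices = [x for x in range(4) if x != a]
        b = b_choices[int(rng.integers(3))]
        founder_b[c] = b
        variants_a.append(str(_BASES[a]))
        variants_b.append(str(_BASES[b]))

    protected = set() if cfg.erode_by_substitution else diag_set

    sub_log: list[Substitution] = []
    conv_log: list[ConversionEvent] = []
    state: dict[int, tuple[np.ndarray, np.ndarray]] = {
        id(tree.seed_node): (founder_a, founder_b)
    }

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length or 0.0
        branch = _branch_label(node)
        seq_a, seq_b = state[id(node.parent_node)]
        # substitutions first, copy A before copy B
        n_a = int(rng.poisson(cfg.sub_rate * bl * seq_len))
        seq_a = _mutate(seq_a, n_a, rng, protected, branch, "A", sub_log)
        n_b = int(rng.poisson(cfg.sub_rate * bl * seq_len))
        seq_b = _mutate(seq_b, n_b, rng, protected, branch, "B", sub_log)
        # then conversions: events drawn per copy, direction uniform
        n_events = int(rng.poisson(cfg.conv_rate * bl)) + int(
            rng.poisson(cfg.conv_rate * bl)
        )
        for _ in range(n_events):
            tract = int(rng.geometric(1.0 / cfg.tract_mean))
            pos = int(rng.integers(seq_len))
            end = min(pos + tract, seq_len)
            a_to_b = bool(rng.integers(2))
            if a_to_b:
                seq_b = apply_conversion(seq_a, seq_b, pos, end)
                conv_log.append(ConversionEvent(branch, "A", "B", pos, end))
            else:
                seq_a = apply_conversion(seq_b, seq_a, pos, end)
                conv_log.append(ConversionEvent(branch, "B", "A", pos, end))
        state[id(node)] = (seq_a, seq_b)

    # higher group = clade under each root child
    group_of_species: dict[str, str] = {}
    for gi, child in enumerate(tree.seed_node.child_nodes(), start=1):
        for lf in child.leaf_iter():
            group_of_species[lf.taxon.label] = f"clade{gi}"

    ids, seqs = [], []
    lineage, species_of, dropped = {}, {}, {}
    leaves = list(tree.leaf_node_iter())
    for lf in leaves:
        sp = lf.taxon.label
        seq_a, seq_b = state[id(lf)]
        keep = {"A": seq_a, "B": seq_b}
        if cfg.dropout_p > 0 and rng.random() < cfg.dropout_p:
            lost = "A" if rng.integers(2) == 0 else "B"
            del keep[lost]
            dropped[sp] = lost
        for lin in sorted(keep):
            sid = f"{sp}_{lin}"
            ids.append(sid)
            seqs.append("".join(_BASES[keep[lin]]))
            lineage[sid] = lin
            species_of[sid] = sp

    aln = Alignment(ids, seqs)
    groups = GroupMap(
        species={sid: species_of[sid] for sid in ids},
        group={sid: group_of_species[species_of[sid]] for sid in ids},
    )
    sig = SignatureTable(
        [
            SignatureSite(int(c) + 1, va, vb)
            for c, va, vb in zip(diag, variants_a, variants_b)
        ],
        n_cols=seq_len,
    )
    truth = SimTruth(
        lineage=lineage,
        species_of=species_of,
        diagnostic_columns0=[int(c) for c in diag],
        variants_a=variants_a,
        variants_b=variants_b,
        events=conv_log,
        substitutions=sub_log,
        founder_a="".join(_BASES[founder_a]),
        founder_b="".join(_BASES[founder_b]),
        tree_newick=write_newick(tree),
        dropped=dropped,
    )
    return aln, groups, sig, truth


def signature_retention_truth(aln: Alignment, truth: SimTruth) -> dict[str, int]:
    """Per species: diagnostic columns at which its two copies still differ.

    Species retaining a single copy score 0 — with one sequence there is
    nothing left to diverge.
    """
    by_species: dict[str, list[str]] = {}
    for sid in aln.ids:
        by_species.setdefault(truth.species_of[sid], []).append(sid)
    cols = np.array(truth.diagnostic_columns0, dtype=int)
    out: dict[str, int] = {}
    for sp, sids in sorted(by_species.items()):
        if len(sids) < 2:
            out[sp] = 0
            continue
        a, b = sorted(sids)
        ra = aln.array[aln.index_of(a), cols]
        rb = aln.array[aln.index_of(b), cols]
        out[sp] = int((ra != rb).sum())
    return out


def replay_events(truth: SimTruth) -> dict[str, str]:
    """Re-apply the logged events to the founders; returns seq id -> sequence.

    Independent reconstruction path used to audit the simulator: walking the
    stored tree and replaying the substitution and conversion logs in branch
    order must reproduce the emitted alignment exactly.
    """
    tree = read_newick(truth.tree_newick)
    by_branch_sub: dict[str, list[Substitution]] = {}
    for s in truth.substitutions:
        by_branch_sub.setdefault(s.branch, []).append(s)
    by_branch_conv: dict[str, list[ConversionEvent]] = {}
    for e in truth.events:
        by_branch_conv.setdefault(e.branch, []).append(e)

    root_state = {
        "A": np.array([_BASE_INDEX[c] for c in truth.founder_a]),
        "B": np.array([_BASE_INDEX[c] for c in truth.founder_b]),
    }
    state = {id(tree.seed_node): root_state}
    result: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        branch = _branch_label(node)
        cur = {c: s.copy() for c, s in state[id(node.parent_node)].items()}
        for s in by_branch_sub.get(branch, []):
            cur[s.copy][s.column] = _BASE_INDEX[s.to_base]
        for e in by_branch_conv.get(branch, []):
            cur[e.recipient] = apply_conversion(cur[e.donor], cur[e.recipient], e.start, e.end)
        state[id(node)] = cur
        if node.is_leaf():
            sp = node.taxon.label
            for lin in ("A", "B"):
                sid = f"{sp}_{lin}"
                if sid in truth.lineage:
                    result[sid] = "".join(_BASES[cur[lin]])
    return result


# ---------------------------------------------------------------------------
# Simulation on an arbitrary tree (building block for multi-topology fixtures)

def simulate_on_tree(
    tree: dendropy.Tree,
    n_cols: int,
    sub_rate: float,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve one sequence per leaf along ``tree`` under Jukes–Cantor.

    Used to construct alignments whose different column blocks follow
    different topologies (e.g. recombination-breakpoint fixtures).
    """
    if n_cols < 1:
        raise DataError("n_cols must be >= 1")
    root_seq = rng.integers(4, size=n_cols)
    state = {id(tree.seed_node): root_seq}
    ids, seqs = [], []
    log: list[Substitution] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length or 0.0
        seq = state[id(node.parent_node)]
        n_sub = int(rng.poisson(sub_rate * bl * n_cols))
        seq = _mutate(seq, n_sub, rng, set(), _branch_label(node), "A", log)
        state[id(node)] = seq
        if node.is_leaf():
            ids.append(node.taxon.label)
            seqs.append("".join(_BASES[seq]))
    order = np.argsort(ids)
    return Alignment([ids[i] for i in order], [seqs[i] for i in order])
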