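"""Lineage-signature screen: classify sequences against two paralog-lineage
signatures, pick most-lineage-like representatives per group, and quantify
retained divergence and intermingling.

A signature is a set of diagnostic alignment columns where the two ancient
paralog lineages carry different fixed variants. Gene conversion between
conspecific paralogs reshuffles these variants into mixed ("intermingled")
profiles and can erase a group's signature divergence entirely; the
retention count measures how much of it survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import MISSING_CHARS, Alignment, DataError, GroupMap, SignatureTable

#: Per-column profile symbols: matches lineage A, matches lineage B,
#: matches neither, or gap/N (excluded from counts).
PROFILE_A, PROFILE_B, PROFILE_OTHER, PROFILE_GAP = "A", "B", "o", "-"

Lineage = Literal["A", "B"]


@dataclass(frozen=True)
class SignatureMatch:
    """Per-sequence tally against a signature table."""

    seq_id: str
    n_a: int
    n_b: int
    n_other: int
    n_gap: int
    profile: str  # one symbol per signature column

    def __post_init__(self):
        if self.n_a + self.n_b + self.n_other + self.n_gap != len(self.profile):
            raise ValueError("signature match counts do not sum to profile length")


@dataclass(frozen=True)
class LineageCall:
    """Classification of one sequence: A, B, intermingled, or uninformative."""

    seq_id: str
    label: Literal["A", "B", "intermingled", "uninformative"]
    minority_fraction: float  # nan when uninformative


def match_signature(
    seq: str, sig: SignatureTable, seq_id: str = ""
) -> SignatureMatch:
    """Tally a sequence's characters at the signature columns.

    Exact single-character comparison; a gap or N at a signature column is
    labeled gap and excluded from the A/B/other counts.
    """
    if sig.columns[-1] > len(seq):
        raise DataError(
            f"signature column {sig.columns[-1]} exceeds sequence length {len(seq)}"
        )
    profile = []
    n_a = n_b = n_other = n_gap = 0
    for site in sig.sites:
        ch = seq[site.column - 1]
        if ch in MISSING_CHARS:
            profile.append(PROFILE_GAP)
            n_gap += 1
        elif ch == site.variant_a:
            profile.append(PROFILE_A)
            n_a += 1
        elif ch == site.variant_b:
            profile.append(PROFILE_B)
            n_b += 1
        else:
            profile.append(PROFILE_OTHER)
            n_other += 1
    return SignatureMatch(seq_id, n_a, n_b, n_other, n_gap, "".join(profile))


def call_lineage(m: SignatureMatch, minority_threshold: float = 0.25) -> LineageCall:
    """Assign A/B/intermingled/uninformative from a signature tally.

    A sequence goes to the lineage with more matching variants, but only
    when the minority fraction min(nA, nB)/(nA + nB) stays below the
    threshold; at or above it — or at an exact tie — the sequence is called
    intermingled, the footprint of conversion mixing the two signatures.
    """
    total = m.n_a + m.n_b
    if total == 0:
        return LineageCall(m.seq_id, "uninformative", float("nan"))
    minority = min(m.n_a, m.n_b) / total
    if m.n_a == m.n_b or minority >= minority_threshold:
        return LineageCall(m.seq_id, "intermingled", minority)
    return LineageCall(m.seq_id, "A" if m.n_a > m.n_b else "B", minority)


def most_lineage_like(
    aln: Alignment,
    seq_ids: Sequence[str],
    sig: SignatureTable,
    lineage: Lineage,
) -> str:
    """The id in ``seq_ids`` most similar to one lineage's signature.

    Maximizes the matching-variant count; ties broken by fewer
    opposite-lineage matches, then lexicographically smallest id.
    """
    if lineage not in ("A", "B"):
        raise ValueError(f"lineage must be 'A' or 'B', got {lineage!r}")
    if not seq_ids:
        raise DataError("empty group")
    best_key = None
    best_id = None
    for sid in seq_ids:
        m = match_signature(aln.row(sid), sig, sid)
        own, opp = (m.n_a, m.n_b) if lineage == "A" else (m.n_b, m.n_a)
        key = (-own, opp, sid)
        if best_key is None or key < best_key:
            best_key, best_id = key, sid
    return best_id


def signature_retention(
    aln: Alignment, seq_ids: Sequence[str], sig: SignatureTable
) -> int:
    """Signature columns at which the group's most-A-like and most-B-like
    sequences still differ.

    Columns where either representative has a gap or N are excluded. A
    single-sequence group scores 0: both representatives are that sequence.
    """
    a_id = most_lineage_like(aln, seq_ids, sig, "A")
    b_id = most_lineage_like(aln, seq_ids, sig, "B")
    ra, rb = aln.row(a_id), aln.row(b_id)
    count = 0
    for site in sig.sites:
        ca, cb = ra[site.column - 1], rb[site.column - 1]
        if ca in MISSING_CHARS or cb in MISSING_CHARS:
            continue
        if ca != cb:
            count += 1
    return count


def intermingling_report(
    aln: Alignment,
    groups: GroupMap,
    sig: SignatureTable,
    group_by: str = "species",
    minority_threshold: float = 0.25,
) -> pd.DataFrame:
    """Per-sequence signature profiles and lineage calls, one row per sequence.

    Columns: group, seq_id, profile (A/B/o/- string over signature columns),
    n_a, n_b, n_other, n_gap, call, minority_fraction. Sorted by group then
    id — the tabular counterpart of an intermingling figure.
    """
    rows = []
    for sid in aln.ids:
        m = match_signature(aln.row(sid), sig, sid)
        call = call_lineage(m, minority_threshold)
        rows.append(
            {
                "group": groups.label_for(sid, group_by),
                "seq_id": sid,
                "profile": m.profile,
                "n_a": m.n_a,
                "n_b": m.n_b,
                "n_other": m.n_other,
                "n_gap": m.n_gap,
                "call": call.label,
                "minority_fraction": call.minority_fraction,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["group", "seq_id"], kind="stable").reset_index(drop=True)


def retention_report(
    aln: Alignment,
    groups: GroupMap,
    sig: SignatureTable,
    group_by: str = "species",
) -> pd.DataFrame:
    """Per-group signature retention with the representative pair.

    Zero marks groups whose two most-lineage-like sequences are fully
    homogenized at the signature (or groups with a single sequence).
    """
    if group_by == "species":
        names, members = groups.species_names(), groups.ids_of_species
    elif group_by == "group":
        names, members = groups.group_names(), groups.ids_of_group
    else:
        raise ValueError(f"group_by must be 'species' or 'group', got {group_by!r}")
    rows = []
    for name in names:
        ids = [sid for sid in members(name) if sid in aln]
        if not ids:
            continue
        a_id = most_lineage_like(aln, ids, sig, "A")
        b_id = most_lineage_like(aln, ids, sig, "B")
        rows.append(
            {
                "group": name,
                "n_seqs": len(ids),
                "most_a_like": a_id,
                "most_b_like": b_id,
                "retention": signature_retention(aln, ids, sig),
            }
        )
    return pd.DataFrame(rows)
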