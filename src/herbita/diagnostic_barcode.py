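"""Species-diagnostic SNP detection and barcode-based classification.

A *diagnostic site* is an alignment column at which every member of a
target species (or species group) carries one state — a base or a gap
(``DEL``) — that no member of any other species carries.  The table of
such sites over the 5.8S-masked ITS1+ITS2 alignment is the species
barcode; a query sequence is classified by concordance with it.

Site positions are reported 1-based over the *masked* columns (ITS1
followed by ITS2), which is how such tables are conventionally printed.

Ambiguity handling: under the default ``"strict"`` policy IUPAC
ambiguity codes and ``N`` are indeterminate — they neither support
fixation nor veto a site.  Under ``"expand"`` an ambiguity code counts
as each of its constituent bases (``R`` is both A and G), both for
fixation candidates and for exclusion; ``N`` stays indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import HerbitaError, SchemaError, SequenceFormatError
from .seq_io_annotation import GAP, LabeledAlignment, LabeledSequence

__all__ = [
    "STATES",
    "ColumnProfile",
    "DiagnosticSite",
    "BarcodeTable",
    "ClassificationResult",
    "profile_columns",
    "find_diagnostic_sites",
    "classify_query",
    "write_barcode_table",
    "read_barcode_table",
]

#: Determinate states, in the fixed order used throughout this module.
STATES = ("A", "C", "G", "T", "DEL")
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}

_IUPAC_EXPANSION = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}

#: Conventional single-letter prefixes for the species of this genus, as
#: used in published barcode tables.
SPECIES_LETTER = {
    "truncata": "T",
    "brachystachys": "B",
    "canariensis": "C",
    "aquatica": "A",
    "coerulescens": "C",
    "minor": "M",
    "paradoxa": "P",
    "californica": "CA",
    "caroliniana": "CR",
    "arundinacea": "AR",
    "lemmonii": "L",
    "angusta": "AN",
}


def _membership(ch: str, policy: str) -> tuple[str, ...]:
    """Determinate states a single residue counts as (empty if none)."""
    if ch in "ACGT":
        return (ch,)
    if ch == GAP:
        return ("DEL",)
    if policy == "expand" and ch in _IUPAC_EXPANSION:
        return tuple(_IUPAC_EXPANSION[ch])
    return ()


@dataclass(frozen=True)
class ColumnProfile:
    """Per-species state counts at one masked alignment column."""

    column: int
    counts: dict  # species -> {state: count} over determinate members
    n_effective: dict  # species -> number of determinate members
    n_ambiguous: dict  # species -> members excluded as indeterminate


@dataclass(frozen=True)
class DiagnosticSite:
    """One diagnostic column of the barcode table."""

    code: str
    target: frozenset
    column: int  # 0-based index into the full alignment
    position_1based: int  # 1-based over masked (ITS1+ITS2) columns
    target_state: str
    other_states: frozenset

    def __post_init__(self):
        if self.target_state in self.other_states:
            raise HerbitaError(
                f"site {self.code}: target state also present outside the target"
            )
        if not self.other_states:
            raise HerbitaError(f"site {self.code}: no states observed outside target")


@dataclass
class BarcodeTable:
    sites: list
    species_without: set
    indistinguishable_groups: list

    def __post_init__(self):
        codes = [s.code for s in self.sites]
        if len(codes) != len(set(codes)):
            raise HerbitaError("duplicate site codes")

    def sites_for(self, species: str) -> list:
        return [s for s in self.sites if species in s.target]

    def singleton_sites(self) -> list:
        return [s for s in self.sites if len(s.target) == 1]


@dataclass(frozen=True)
class ClassificationResult:
    accession: str
    best_species: str | None
    sites_matched: int
    sites_tested: int
    per_species_score: dict  # species -> (matched, tested)
    verdict: str  # assigned | ambiguous | unassigned


class _ColumnTensor:
    """Boolean membership tensor over (member, masked column, state)."""

    def __init__(self, alignment: LabeledAlignment, policy: str = "strict"):
        if len(alignment.species) < 2:
            raise HerbitaError("diagnostic analysis needs >= 2 species")
        self.alignment = alignment
        self.policy = policy
        self.columns = alignment.masked_columns()
        mat = alignment.matrix()[:, self.columns]  # members x masked cols
        n_mem, n_col = mat.shape
        member = np.zeros((n_mem, n_col, len(STATES)), dtype=bool)
        for ch in np.unique(mat):
            states = _membership(str(ch), policy)
            if not states:
                continue
            where = mat == ch
            for s in states:
                member[:, :, _STATE_INDEX[s]] |= where
        self.member = member
        self.species = alignment.species
        self.rows = {
            sp: np.array([i for i, m in enumerate(alignment.members) if m.species == sp])
            for sp in self.species
        }
        # per-species: any member carries state; member contributes iff any state
        self.present = {sp: member[rows].any(axis=0) for sp, rows in self.rows.items()}
        contributing = member.any(axis=2)  # member x col
        self.n_det = {sp: contributing[rows].sum(axis=0) for sp, rows in self.rows.items()}
        # fixation candidates: states carried by every contributing member
        self.candidate = {}
        for sp, rows in self.rows.items():
            sub = member[rows]  # k x col x state
            contrib = sub.any(axis=2)[:, :, None]  # k x col x 1
            self.candidate[sp] = np.where(contrib, sub, True).all(axis=0) & (
                self.n_det[sp][:, None] > 0
            )


def profile_columns(alignment: LabeledAlignment, policy: str = "strict") -> list[ColumnProfile]:
    """Tally determinate states per species for every masked column."""
    t = _ColumnTensor(alignment, policy)
    mat = alignment.matrix()[:, t.columns]
    profiles = []
    for j, col in enumerate(t.columns):
        counts: dict[str, dict[str, int]] = {}
        n_eff: dict[str, int] = {}
        n_amb: dict[str, int] = {}
        for sp, rows in t.rows.items():
            tally: dict[str, int] = {}
            amb = 0
            for ch in mat[rows, j]:
                states = _membership(str(ch), "strict")
                if states:
                    tally[states[0]] = tally.get(states[0], 0) + 1
                else:
                    amb += 1
            counts[sp] = tally
            n_eff[sp] = sum(tally.values())
            n_amb[sp] = amb
        profiles.append(ColumnProfile(int(col), counts, n_eff, n_amb))
    return profiles


def assign_codes(
    raw_sites: Sequence[tuple[frozenset, int, int, str, frozenset]]
) -> list[DiagnosticSite]:
    """Build coded :class:`DiagnosticSite` objects from raw tuples
    ``(target, column, position_1based, target_state, other_states)``.

    Codes use the conventional per-species letter prefixes with an
    ordinal in ascending column order; group sites join the member
    letters with ``-``.  Prefix collisions between distinct targets are
    resolved by extending to more letters of the epithet.
    """

    def epithet(sp: str) -> str:
        return sp.split()[-1].lower()

    def letters(sp: str) -> str:
        return "".join(ch for ch in epithet(sp) if ch.isalpha()).upper()

    def alpha_index(i: int) -> str:
        out = ""
        while True:
            out = chr(ord("A") + i % 26) + out
            i = i // 26 - 1
            if i < 0:
                return out

    def base_letter(sp: str) -> str | None:
        known = SPECIES_LETTER.get(epithet(sp))
        if known:
            return known
        return letters(sp)[:1] or None

    # prefixes stay all-letter (ordinals are digits), so codes parse
    # unambiguously and distinct prefixes can never collide
    targets = sorted({t for t, *_ in raw_sites}, key=lambda t: sorted(t))
    prefix: dict[frozenset, str] = {}
    synthetic = 0
    for tgt in targets:
        parts = [base_letter(sp) for sp in sorted(tgt)]
        if any(p is None for p in parts):
            prefix[tgt] = "SP" + alpha_index(synthetic)
            synthetic += 1
        else:
            prefix[tgt] = "-".join(parts)
    # resolve equal prefixes by lengthening epithet letters, then padding
    seen: set[str] = set()
    for tgt in targets:
        p = prefix[tgt]
        if p in seen:
            if len(tgt) == 1:
                (sp,) = tgt
                k = 2
                p = letters(sp)[:k] or p
                while p in seen:
                    k += 1
                    longer = letters(sp)[:k]
                    p = longer if len(longer) == k else p + "X"
            else:
                while p in seen:
                    p += "X"
            prefix[tgt] = p
        seen.add(p)
    ordinal: dict[frozenset, int] = {t: 0 for t in targets}
    sites = []
    for tgt, column, pos, state, others in sorted(raw_sites, key=lambda r: (r[1], sorted(r[0]))):
        ordinal[tgt] += 1
        sites.append(
            DiagnosticSite(
                code=f"{prefix[tgt]}{ordinal[tgt]}",
                target=tgt,
                column=column,
                position_1based=pos,
                target_state=state,
                other_states=others,
            )
        )
    return sites


def find_diagnostic_sites(
    alignment: LabeledAlignment,
    targets: Sequence[Iterable[str]] | None = None,
    policy: str = "strict",
    min_coverage: int = 1,
) -> BarcodeTable:
    """Scan every masked column for species- or group-diagnostic states.

    A column yields a site for target set ``S`` when (i) all determinate
    members of ``S`` share a single state, (ii) no determinate member
    outside ``S`` carries that state, and (iii) every species has at
    least ``min_coverage`` determinate members at the column.  Default
    targets are all single species; supply explicit sets to search for
    clade-shared sites.
    """
    t = _ColumnTensor(alignment, policy)
    species_set = set(t.species)
    if targets is None:
        target_sets = [frozenset([sp]) for sp in t.species]
    else:
        target_sets = []
        for tgt in targets:
            fs = frozenset(tgt)
            if not fs:
                raise HerbitaError("empty target set")
            missing = fs - species_set
            if missing:
                raise HerbitaError(
                    f"target species not in alignment: {', '.join(sorted(missing))}"
                )
            target_sets.append(fs)

    n_col = len(t.columns)
    coverage_ok = np.ones(n_col, dtype=bool)
    for sp in t.species:
        coverage_ok &= t.n_det[sp] >= min_coverage

    raw: list[tuple[frozenset, int, int, str, frozenset]] = []
    for tgt in target_sets:
        inside = sorted(tgt)
        outside = [sp for sp in t.species if sp not in tgt]
        if not outside:
            raise HerbitaError(f"target {inside} covers every species")
        cand = t.candidate[inside[0]].copy()
        for sp in inside[1:]:
            cand &= t.candidate[sp]
        out_present = np.zeros_like(cand)
        for sp in outside:
            out_present |= t.present[sp]
        ok = cand & ~out_present  # col x state
        ok &= coverage_ok[:, None]
        ok &= out_present.any(axis=1)[:, None]  # other_states must be non-empty
        for j, si in zip(*np.nonzero(ok)):
            state = STATES[si]
            others = frozenset(
                STATES[k] for k in np.nonzero(out_present[j])[0]
            )
            raw.append((tgt, int(t.columns[j]), int(j) + 1, state, others))

    # keep at most one site per (target, column): prefer the
    # lexicographically smallest state (only reachable under "expand")
    dedup: dict[tuple[frozenset, int], tuple] = {}
    for entry in sorted(raw, key=lambda r: (r[1], sorted(r[0]), r[3])):
        dedup.setdefault((entry[0], entry[1]), entry)
    sites = assign_codes(list(dedup.values()))

    with_singleton = {next(iter(s.target)) for s in sites if len(s.target) == 1}
    species_without = species_set - with_singleton
    groups = _indistinguishable_pairs(t, coverage_ok)
    return BarcodeTable(sites, species_without, groups)


def _indistinguishable_pairs(t: _ColumnTensor, coverage_ok: np.ndarray) -> list[frozenset]:
    """Species pairs with no fixed state difference at any masked column."""
    pairs = []
    species = t.species
    for i, a in enumerate(species):
        fixed_a = t.candidate[a] & (t.n_det[a][:, None] > 0)
        for b in species[i + 1:]:
            fixed_b = t.candidate[b] & (t.n_det[b][:, None] > 0)
            both = (t.n_det[a] > 0) & (t.n_det[b] > 0)
            # a fixed difference: each fixed for some state, sharing none
            a_any = fixed_a.any(axis=1)
            b_any = fixed_b.any(axis=1)
            shared = (fixed_a & fixed_b).any(axis=1)
            differs = both & a_any & b_any & ~shared
            if not differs.any():
                pairs.append(frozenset([a, b]))
    return pairs


def classify_query(
    query: LabeledSequence,
    table: BarcodeTable,
    policy: str = "strict",
) -> ClassificationResult:
    """Assign a species to a query aligned to the barcode's coordinates.

    For every species targeted by the table, sites where the query is
    determinate count as tested and as matched when the query carries the
    target state.  The verdict is ``assigned`` when a single species
    matches every site it was tested on and out-matches all others,
    ``ambiguous`` on ties (or a best species with mismatches), and
    ``unassigned`` when nothing matches.
    """
    max_col = max((s.column for s in table.sites), default=-1)
    if len(query.residues) <= max_col:
        raise SequenceFormatError(
            f"query {query.accession} shorter than the barcode alignment "
            f"({len(query.residues)} <= {max_col})"
        )
    score: dict[str, list[int]] = {}
    for site in table.sites:
        states = _membership(query.residues[site.column], policy)
        if not states:
            continue
        matched = site.target_state in states
        for sp in site.target:
            entry = score.setdefault(sp, [0, 0])
            entry[1] += 1
            entry[0] += int(matched)
    per_species = {sp: (m, t_) for sp, (m, t_) in score.items()}
    if not per_species or all(m == 0 for m, _ in per_species.values()):
        tested = sum(t_ for _, t_ in per_species.values())
        return ClassificationResult(query.accession, None, 0, tested, per_species, "unassigned")
    best_matched = max(m for m, _ in per_species.values())
    best = [sp for sp, (m, _) in per_species.items() if m == best_matched]
    if len(best) == 1 and per_species[best[0]][0] == per_species[best[0]][1]:
        sp = best[0]
        m, t_ = per_species[sp]
        return ClassificationResult(query.accession, sp, m, t_, per_species, "assigned")
    best_sp = None if len(best) > 1 else best[0]
    m, t_ = (per_species[best_sp] if best_sp else (best_matched,
             max(t_ for _, t_ in per_species.values())))
    return ClassificationResult(query.accession, best_sp, m, t_, per_species, "ambiguous")


def write_barcode_table(table: BarcodeTable, path: str | Path) -> None:
    """Write the site table as TSV (positions 1-based over masked columns)."""
    lines = ["code\tspecies\tposition_1based\ttarget_state\tother_states"]
    for s in table.sites:
        lines.append(
            "\t".join(
                [
                    s.code,
                    ";".join(sorted(s.target)),
                    str(s.position_1based),
                    s.target_state,
                    "|".join(sorted(s.other_states)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_barcode_table(
    path: str | Path, column_mask: np.ndarray | None = None
) -> BarcodeTable:
    """Read a barcode TSV back; a mask restores full-alignment columns.

    Without ``column_mask`` the site ``column`` falls back to the masked
    position, which is only valid against an already-masked alignment.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != [
        "code", "species", "position_1based", "target_state", "other_states"
    ]:
        raise SchemaError(f"{path}: not a barcode table")
    masked_cols = None
    if column_mask is not None:
        masked_cols = np.flatnonzero(np.asarray(column_mask, dtype=bool))
    sites = []
    for ln in lines[1:]:
        code, species, pos, state, others = ln.split("\t")
        pos_i = int(pos)
        column = int(masked_cols[pos_i - 1]) if masked_cols is not None else pos_i - 1
        sites.append(
            DiagnosticSite(
                code=code,
                target=frozenset(species.split(";")),
                column=column,
                position_1based=pos_i,
                target_state=state,
                other_states=frozenset(others.split("|")),
            )
        )
    singles = {next(iter(s.target)) for s in sites if len(s.target) == 1}
    return BarcodeTable(sites, set(), [])
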