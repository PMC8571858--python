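"""Shared fixtures and small independent oracles used across the suite."""

import itertools

import numpy as np
import pytest

from herbita.seq_io_annotation import GAP, LabeledAlignment, LabeledSequence
from herbita.specimen_qc import packaged_fresh_records, packaged_herbarium_records


@pytest.fixture(scope="session")
def herbarium_records():
    return packaged_herbarium_records()


@pytest.fixture(scope="session")
def fresh_records():
    return packaged_fresh_records()


def make_alignment(rows, mask=None):
    """Build a LabeledAlignment from (accession, species, residues) rows."""
    members = [LabeledSequence(a, sp, seq) for a, sp, seq in rows]
    return LabeledAlignment(members, mask)


@pytest.fixture
def toy_two_species():
    return make_alignment(
        [
            ("x1", "Species X", "ACG"),
            ("x2", "Species X", "ACG"),
            ("y1", "Species Y", "ATG"),
            ("y2", "Species Y", "ATG"),
        ]
    )


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_sites(alignment, targets=None, policy="strict", min_coverage=1):
    """Naive per-column diagnostic-site scan, independent of the package
    implementation: literal conditions (i) fixation inside the target,
    (ii) exclusion outside, (iii) coverage, checked state by state."""
    expand = {
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    }

    def states_of(ch):
        if ch in "ACGT":
            return {ch}
        if ch == GAP:
            return {"DEL"}
        if policy == "expand" and ch in expand:
            return set(expand[ch])
        return set()

    species = alignment.species
    if targets is None:
        targets = [frozenset([sp]) for sp in species]
    else:
        targets = [frozenset(t) for t in targets]
    by_species = {sp: [m for m in alignment.members if m.species == sp] for sp in species}
    found = set()
    for pos, col in enumerate(alignment.masked_columns(), start=1):
        per_member = {
            sp: [states_of(m.residues[col]) for m in mems]
            for sp, mems in by_species.items()
        }
        det_count = {sp: sum(1 for s in sets if s) for sp, sets in per_member.items()}
        if any(det_count[sp] < min_coverage for sp in species):
            continue
        for tgt in targets:
            inside = [s for sp in tgt for s in per_member[sp] if s]
            outside = set().union(
                *(s for sp in species if sp not in tgt for s in per_member[sp])
            )
            if not inside or not outside:
                continue
            shared = set.intersection(*inside)
            diagnostic = sorted(shared - outside)
            if diagnostic:
                found.add((tgt, int(col), pos, diagnostic[0], frozenset(outside)))
    return found


def site_key(table_or_sites):
    sites = getattr(table_or_sites, "sites", table_or_sites)
    return {
        (s.target, s.column, s.position_1based, s.target_state, s.other_states)
        for s in sites
    }


def random_alignment(rng, n_species=None, members=None, n_cols=None,
                     gap_rate=0.05, n_rate=0.02, ambig_rate=0.0):
    """A fully random alignment (no phylogenetic structure) for oracle
    equivalence tests."""
    n_species = n_species or int(rng.integers(2, 13))
    members = members or int(rng.integers(1, 21))
    n_cols = n_cols or int(rng.integers(50, 701))
    chars = np.array(list("ACGT-NR"))
    probs = np.array([1, 1, 1, 1, 0, 0, 0], dtype=float)
    probs[4] = 4 * gap_rate / (1 - gap_rate - n_rate - ambig_rate)
    probs[5] = 4 * n_rate / (1 - gap_rate - n_rate - ambig_rate)
    probs[6] = 4 * ambig_rate / (1 - gap_rate - n_rate - ambig_rate) if ambig_rate else 0
    probs /= probs.sum()
    rows = []
    k = 0
    for s in range(n_species):
        # species share a loose template so some columns are near-fixed
        template = rng.choice(chars[:4], size=n_cols)
        for _ in range(members):
            k += 1
            seq = template.copy()
            resample = rng.random(n_cols) < 0.3
            seq[resample] = rng.choice(chars, size=int(resample.sum()), p=probs)
            rows.append((f"R{k:03d}.1", f"Species {s:02d}", "".join(seq)))
    mask = rng.random(n_cols) > 0.2
    if not mask.any():
        mask[0] = True
    return make_alignment(rows, mask)


# -- additive trees for NJ correctness --------------------------------------


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree; returns (distance matrix, split set).

    Built by sequential leaf attachment with positive branch lengths;
    distances are exact path sums, splits are the non-trivial
    bipartitions (frozenset-of-frozensets over leaf names).
    """
    names = [f"L{i}" for i in range(n_leaves)]
    adj = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def drop_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    inner0 = "I0"
    nxt = 1
    for i in range(3):
        add_edge(names[i], inner0, float(rng.uniform(0.05, 1.0)))
    edges = [(names[i], inner0) for i in range(3)]
    for leaf in names[3:]:
        a, b = edges[int(rng.integers(len(edges)))]
        w = adj[a][b]
        mid = f"I{nxt}"
        nxt += 1
        f = float(rng.uniform(0.2, 0.8))
        drop_edge(a, b)
        add_edge(a, mid, w * f)
        add_edge(mid, b, w * (1 - f))
        add_edge(leaf, mid, float(rng.uniform(0.05, 1.0)))
        edges.remove((a, b))
        edges += [(a, mid), (mid, b), (leaf, mid)]

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(names):
        d = dists_from(a)
        for j, b in enumerate(names):
            D[i, j] = d[b]

    all_leaves = frozenset(names)
    splits = set()
    for a, b in edges:
        # side of leaf names reachable from a without crossing (a, b)
        w = adj[a][b]
        drop_edge(a, b)
        seen = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        add_edge(a, b, w)
        side = frozenset(x for x in seen if x in all_leaves)
        if 1 < len(side) < n_leaves - 1:
            splits.add(frozenset([side, all_leaves - side]))
    return names, D, splits
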