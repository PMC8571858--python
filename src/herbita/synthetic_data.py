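"""Synthetic ITS alignments and specimen metadata with known ground truth.

The generator emulates the data structure of a multi-species ITS
barcoding study: one ~600 nt ITS1+5.8S+ITS2 template per species,
several accessions per species with light within-species polymorphism,
planted species- or group-diagnostic substitutions and deletions,
optionally mislabeled accessions, and a herbarium metadata table in
which DNA concentration is age-independent while amplification success
decays with specimen age.

Inter-species divergence is modelled as substitutions shared by at least
two template lineages (species tied together in a planted group target
share one lineage and never diverge from each other).  Private fixed
states therefore arise *only* at planted columns, which makes the
recorded truth exhaustive: a site caller with perfect precision and
recall will find exactly the planted sites.  Gap columns arise only from
planted DEL sites; there is no indel process.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .diagnostic_barcode import DiagnosticSite, assign_codes
from .errors import ConfigError
from .seq_io_annotation import (
    GAP,
    ItsAnnotation,
    LabeledAlignment,
    LabeledSequence,
    save_annotations,
    write_labeled_fasta,
)
from .specimen_qc import SpecimenRecord

__all__ = [
    "PlantedSite",
    "MetadataConfig",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_alignment",
    "simulate_specimen_metadata",
    "write_fixture_bundle",
    "load_fixture_bundle",
    "phalaris_study_config",
]

#: Default species names for up to twelve simulated species.
DEFAULT_SPECIES = (
    "Phalaris truncata",
    "Phalaris brachystachys",
    "Phalaris canariensis",
    "Phalaris aquatica",
    "Phalaris coerulescens",
    "Phalaris minor",
    "Phalaris paradoxa",
    "Phalaris californica",
    "Phalaris caroliniana",
    "Phalaris arundinacea",
    "Phalaris lemmonii",
    "Phalaris angusta",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    """A diagnostic state to plant: ``target`` species (one or more) get
    ``state`` (a base or ``DEL``) at ``offset`` within ``region``."""

    target: tuple
    region: str  # "its1" | "its2"
    offset: int
    state: str  # A/C/G/T or DEL

    def __post_init__(self):
        if self.region not in ("its1", "its2"):
            raise ConfigError(f"planted sites go in its1 or its2, not {self.region!r}")
        if self.state not in ("A", "C", "G", "T", "DEL"):
            raise ConfigError(f"bad planted state {self.state!r}")
        if not self.target:
            raise ConfigError("planted site with empty target")


@dataclass(frozen=True)
class MetadataConfig:
    """Generating model for the specimen metadata table."""

    n_specimens: int = 52
    year_range: tuple = (1882, 2001)
    #: P(amplify) = logistic(intercept + slope * (year - reference_year))
    amplification_logistic: tuple = (1.0, 0.05)
    logistic_reference_year: int = 1950
    #: DNA concentration ~ lognormal(mu, sigma), independent of year
    conc_lognormal: tuple = (2.7, 0.9)
    od_260_280: tuple = (1.95, 0.15)
    od_260_230: tuple = (1.9, 0.5)
    full_seq_given_amplified: float = 0.75
    undated_count: int = 1
    outlier_count: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_species: int = 12
    members_per_species: int | tuple = 4
    its1_len: int = 220
    r58s_len: int = 160
    its2_len: int = 220
    planted_sites: tuple = ()
    inter_species_divergence: float = 0.03
    within_species_polymorphism: float = 0.002
    mislabel_count: int = 0
    missing_data_rate: float = 0.0
    species_names: tuple | None = None
    metadata: MetadataConfig = field(default_factory=MetadataConfig)

    def __post_init__(self):
        for name in ("inter_species_divergence", "within_species_polymorphism",
                     "missing_data_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        for name in ("its1_len", "r58s_len", "its2_len"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_species < 2:
            raise ConfigError("need >= 2 species")

    # -- derived -----------------------------------------------------
    @property
    def species(self) -> list[str]:
        if self.species_names is not None:
            if len(self.species_names) != self.n_species:
                raise ConfigError("species_names length != n_species")
            return list(self.species_names)
        names = list(DEFAULT_SPECIES[: self.n_species])
        for i in range(len(names), self.n_species):
            names.append(f"Species {i + 1:02d}")
        return names

    @property
    def total_length(self) -> int:
        return self.its1_len + self.r58s_len + self.its2_len

    def members_of(self, species_index: int) -> int:
        if isinstance(self.members_per_species, int):
            return self.members_per_species
        return int(self.members_per_species[species_index])

    def region_bounds(self) -> dict:
        c1, c2 = self.its1_len, self.r58s_len
        return {
            "its1": (0, c1),
            "r58s": (c1, c1 + c2),
            "its2": (c1 + c2, self.total_length),
        }

    def planted_column(self, site: PlantedSite) -> int:
        start, end = self.region_bounds()[site.region]
        col = start + site.offset
        if not (start <= col < end):
            raise ConfigError(
                f"planted offset {site.offset} outside {site.region} bounds"
            )
        return col

    def masked_position(self, column: int) -> int:
        """1-based position over ITS1+ITS2 (5.8S excluded) columns."""
        b = self.region_bounds()
        if column < b["its1"][1]:
            return column + 1
        if column >= b["its2"][0]:
            return self.its1_len + (column - b["its2"][0]) + 1
        raise ConfigError("column falls inside the 5.8S region")

    # -- (de)serialisation -------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_sites"] = [dataclasses.asdict(p) for p in self.planted_sites]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["planted_sites"] = tuple(
            PlantedSite(target=tuple(p["target"]), region=p["region"],
                        offset=p["offset"], state=p["state"])
            for p in d.get("planted_sites", [])
        )
        if d.get("species_names") is not None:
            d["species_names"] = tuple(d["species_names"])
        if isinstance(d.get("members_per_species"), list):
            d["members_per_species"] = tuple(d["members_per_species"])
        md = d.get("metadata", {})
        if isinstance(md, Mapping):
            md = dict(md)
            for key in ("year_range", "amplification_logistic", "conc_lognormal",
                        "od_260_280", "od_260_230"):
                if key in md:
                    md[key] = tuple(md[key])
            d["metadata"] = MetadataConfig(**md)
        return cls(**d)


@dataclass
class SimulationTruth:
    true_sites: list
    true_labels: dict  # accession -> generating species
    mislabeled: set
    reference_annotation: ItsAnnotation
    member_annotations: dict  # accession -> ItsAnnotation (ungapped coords)


def _lineages(config: SimulationConfig) -> list[tuple[str, ...]]:
    """Species grouped so that planted group targets share one lineage."""
    species = config.species
    parent = {sp: sp for sp in species}

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for site in config.planted_sites:
        first = site.target[0]
        for sp in site.target[1:]:
            if sp not in parent or first not in parent:
                raise ConfigError(f"planted target references unknown species {site.target}")
            parent[find(sp)] = find(first)
    groups: dict[str, list[str]] = {}
    for sp in species:
        groups.setdefault(find(sp), []).append(sp)
    return [tuple(g) for g in groups.values()]


def simulate_alignment(
    config: SimulationConfig,
) -> tuple[LabeledAlignment, SimulationTruth]:
    """Generate a labeled alignment plus its ground truth, deterministically.

    The emitted alignment's column mask already excludes the 5.8S block
    (re-deriving it via annotation transfer and masking is idempotent).
    """
    rng = np.random.default_rng(config.seed)
    L = config.total_length
    species = config.species
    bounds = config.region_bounds()

    planted_cols: dict[int, list[PlantedSite]] = {}
    for site in config.planted_sites:
        col = config.planted_column(site)
        for other in planted_cols.get(col, []):
            if other.state == site.state and set(other.target) != set(site.target):
                raise ConfigError(
                    f"planted collision at column {col}: state {site.state} "
                    f"claimed by {other.target} and {site.target}"
                )
        planted_cols.setdefault(col, []).append(site)

    root = rng.choice(_BASES, size=L)
    lineages = _lineages(config)
    lineage_of = {sp: i for i, grp in enumerate(lineages) for sp in grp}
    templates = {sp: root.copy() for sp in species}

    # shared divergence: substitutions carried by >= 2 lineages per side
    # (when possible), so no lineage acquires a private fixed state
    n_lin = len(lineages)
    min_side = 2 if n_lin >= 4 else 1
    for col in range(L):
        if col in planted_cols:
            continue
        if rng.random() >= config.inter_species_divergence:
            continue
        for _ in range(64):
            side = rng.random(n_lin) < 0.5
            if min_side <= side.sum() <= n_lin - min_side:
                break
        else:
            continue
        alt = rng.choice([b for b in "ACGT" if b != root[col]])
        for i, grp in enumerate(lineages):
            if side[i]:
                for sp in grp:
                    templates[sp][col] = alt

    # planted diagnostic states
    for col, sites in planted_cols.items():
        states = {s.state for s in sites}
        background = root[col]
        if background in states:
            choices = [b for b in "ACGT" if b not in states]
            if not choices:
                raise ConfigError(f"no background base available at column {col}")
            background = rng.choice(choices)
        targeted = set()
        for site in sites:
            value = GAP if site.state == "DEL" else site.state
            for sp in site.target:
                if sp in targeted:
                    raise ConfigError(
                        f"species {sp} targeted twice at column {col}"
                    )
                targeted.add(sp)
                templates[sp][col] = value
        for sp in species:
            if sp not in targeted:
                templates[sp][col] = background

    # members
    members: list[LabeledSequence] = []
    true_labels: dict[str, str] = {}
    planted_col_set = set(planted_cols)
    free_cols = np.array([c for c in range(L) if c not in planted_col_set])
    counter = 0
    member_rows: list[np.ndarray] = []
    for si, sp in enumerate(species):
        for _ in range(config.members_of(si)):
            counter += 1
            seq = templates[sp].copy()
            if config.within_species_polymorphism > 0 and free_cols.size:
                hits = free_cols[rng.random(free_cols.size) < config.within_species_polymorphism]
                for col in hits:
                    seq[col] = rng.choice([b for b in "ACGT" if b != seq[col]])
            accession = f"SYN{counter:04d}.1"
            true_labels[accession] = sp
            member_rows.append(seq)

    accessions = list(true_labels)
    labels = dict(true_labels)
    mislabeled: set[str] = set()
    if config.mislabel_count:
        if config.mislabel_count > len(accessions):
            raise ConfigError("mislabel_count exceeds member count")
        chosen = rng.choice(len(accessions), size=config.mislabel_count, replace=False)
        for k in chosen:
            acc = accessions[int(k)]
            wrong = rng.choice([s for s in species if s != true_labels[acc]])
            labels[acc] = str(wrong)
            mislabeled.add(acc)

    if config.missing_data_rate > 0:
        for seq in member_rows:
            hits = np.flatnonzero(
                (rng.random(L) < config.missing_data_rate) & (seq != GAP)
            )
            seq[hits] = "N"

    members = [
        LabeledSequence(acc, labels[acc], "".join(row))
        for acc, row in zip(accessions, member_rows)
    ]
    mask = np.ones(L, dtype=bool)
    mask[bounds["r58s"][0]: bounds["r58s"][1]] = False
    alignment = LabeledAlignment(members, mask)

    # per-member annotations in ungapped coordinates
    member_annotations = {}
    for m in members:
        c1 = sum(1 for ch in m.residues[: bounds["its1"][1]] if ch != GAP)
        c2 = sum(1 for ch in m.residues[bounds["r58s"][0]: bounds["r58s"][1]] if ch != GAP)
        c3 = sum(1 for ch in m.residues[bounds["its2"][0]:] if ch != GAP)
        member_annotations[m.accession] = ItsAnnotation(
            (0, c1), (c1, c1 + c2), (c1 + c2, c1 + c2 + c3)
        )

    truth_sites = _truth_sites(config, alignment, true_labels, planted_cols)
    truth = SimulationTruth(
        true_sites=truth_sites,
        true_labels=true_labels,
        mislabeled=mislabeled,
        reference_annotation=ItsAnnotation(
            bounds["its1"], bounds["r58s"], bounds["its2"]
        ),
        member_annotations=member_annotations,
    )
    _self_check(alignment, truth, true_labels)
    return alignment, truth


def _truth_sites(config, alignment, true_labels, planted_cols) -> list[DiagnosticSite]:
    """Coded truth sites with other_states read off the emitted members."""
    mat = alignment.matrix()
    rows_of: dict[str, list[int]] = {}
    for i, m in enumerate(alignment.members):
        rows_of.setdefault(true_labels[m.accession], []).append(i)
    raw = []
    for col, sites in planted_cols.items():
        for site in sites:
            others = set()
            outside_rows = [
                r for sp, rows in rows_of.items() if sp not in site.target for r in rows
            ]
            for r in outside_rows:
                ch = mat[r, col]
                if ch in "ACGT":
                    others.add(str(ch))
                elif ch == GAP:
                    others.add("DEL")
            raw.append(
                (
                    frozenset(site.target),
                    col,
                    config.masked_position(col),
                    site.state,
                    frozenset(others),
                )
            )
    return assign_codes(raw)


def _self_check(alignment, truth, true_labels) -> None:
    """Verify each planted site is diagnostic on the emitted alignment."""
    mat = alignment.matrix()
    for site in truth.true_sites:
        want = GAP if site.target_state == "DEL" else site.target_state
        for i, m in enumerate(alignment.members):
            sp = true_labels[m.accession]
            ch = str(mat[i, site.column])
            if sp in site.target:
                if ch not in (want, "N"):
                    raise ConfigError(
                        f"self-check: {site.code} not fixed in target ({m.accession})"
                    )
            elif ch == want:
                raise ConfigError(
                    f"self-check: {site.code} state leaks outside target ({m.accession})"
                )


def simulate_specimen_metadata(config: SimulationConfig) -> list[SpecimenRecord]:
    """Generate a herbarium-style metadata table from the configured model.

    DNA concentration is lognormal and independent of collection year
    (zero-slope truth for the age regression); amplification success
    follows a logistic in collection year, so old specimens fail more.
    """
    md = config.metadata
    rng = np.random.default_rng(config.seed)
    y0, y1 = md.year_range
    if y1 < y0:
        raise ConfigError("invalid year range")
    b0, b1 = md.amplification_logistic
    species = config.species
    records = []
    for i in range(md.n_specimens):
        year = int(rng.integers(y0, y1 + 1))
        conc = float(rng.lognormal(md.conc_lognormal[0], md.conc_lognormal[1]))
        od280 = float(rng.normal(*md.od_260_280))
        od230 = float(rng.normal(*md.od_260_230))
        p_amp = 1.0 / (1.0 + math.exp(-(b0 + b1 * (year - md.logistic_reference_year))))
        amplified = bool(rng.random() < p_amp)
        full = bool(amplified and rng.random() < md.full_seq_given_amplified)
        undated = i >= md.n_specimens - md.undated_count
        if md.outlier_count and i < md.outlier_count:
            od230 = float(rng.normal(0.0, 3.0))
        records.append(
            SpecimenRecord(
                specimen_id=f"SIM-{i + 1:04d}",
                species=species[i % len(species)],
                collection_date=None,
                collection_year=None if undated else year,
                dna_conc=round(conc, 3),
                od_260_280=round(od280, 3),
                od_260_230=round(od230, 3),
                amplified=amplified,
                full_sequence=full,
                genbank_accession=f"SYNMD{i + 1:04d}.1" if full else None,
                source_class="herbarium",
            )
        )
    return records


def phalaris_study_config(seed: int) -> SimulationConfig:
    """A 12-species configuration whose planted-site structure mirrors the
    published barcode table: per-species singleton counts
    (5, 0, 0, 5, 3, 3, 1, 2, 3, 6, 0, 0) in :data:`DEFAULT_SPECIES` order,
    nine shared sites for the indistinguishable pair, one deletion site,
    and two species with no sites at all."""
    singleton_counts = {
        "Phalaris truncata": 5,
        "Phalaris aquatica": 5,
        "Phalaris coerulescens": 3,
        "Phalaris minor": 3,
        "Phalaris paradoxa": 1,
        "Phalaris californica": 2,
        "Phalaris caroliniana": 3,
        "Phalaris arundinacea": 6,
    }
    pair = ("Phalaris brachystachys", "Phalaris canariensis")
    rng = np.random.default_rng(seed)
    probe = SimulationConfig(seed=seed)
    offsets = {
        "its1": list(range(probe.its1_len)),
        "its2": list(range(probe.its2_len)),
    }
    planted = []
    used: set[tuple[str, int]] = set()

    def draw(region):
        while True:
            off = int(rng.choice(offsets[region]))
            if (region, off) not in used:
                used.add((region, off))
                return off

    for sp, count in singleton_counts.items():
        for k in range(count):
            region = "its1" if rng.random() < 0.5 else "its2"
            state = "DEL" if (sp == "Phalaris coerulescens" and k == 0) else str(
                rng.choice(list("ACGT"))
            )
            planted.append(PlantedSite((sp,), region, draw(region), state))
    for _ in range(9):
        region = "its1" if rng.random() < 0.5 else "its2"
        planted.append(PlantedSite(pair, region, draw(region), str(rng.choice(list("ACGT")))))
    return SimulationConfig(
        seed=seed,
        n_species=12,
        members_per_species=4,
        planted_sites=tuple(planted),
        inter_species_divergence=0.04,
        within_species_polymorphism=0.0,
        mislabel_count=0,
        missing_data_rate=0.0,
    )


# ---------------------------------------------------------------------------
# fixture bundles


def _records_to_csv(records: Sequence[SpecimenRecord]) -> str:
    header = (
        "specimen_id,species,collection_date,dna_conc_ng_ul,od_260_280,"
        "od_260_230,amplified,full_sequence,genbank_accession,source_class"
    )
    lines = [header]
    for r in records:
        if r.collection_date is not None:
            date = r.collection_date.isoformat()
        elif r.collection_year is not None:
            date = str(r.collection_year)
        else:
            date = "ND"
        lines.append(
            ",".join(
                [
                    r.specimen_id,
                    r.species,
                    date,
                    f"{r.dna_conc:.3f}",
                    f"{r.od_260_280:.3f}",
                    f"{r.od_260_230:.3f}",
                    "+" if r.amplified else "-",
                    "+" if r.full_sequence else "-",
                    r.genbank_accession or "",
                    r.source_class,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _truth_to_dict(truth: SimulationTruth) -> dict:
    return {
        "true_sites": [
            {
                "code": s.code,
                "target": sorted(s.target),
                "column": s.column,
                "position_1based": s.position_1based,
                "target_state": s.target_state,
                "other_states": sorted(s.other_states),
            }
            for s in truth.true_sites
        ],
        "true_labels": truth.true_labels,
        "mislabeled": sorted(truth.mislabeled),
        "reference_annotation": {
            k: list(v) for k, v in truth.reference_annotation.regions().items()
        },
    }


def _truth_from_dict(d: Mapping) -> SimulationTruth:
    ann = d["reference_annotation"]
    sites = [
        DiagnosticSite(
            code=s["code"],
            target=frozenset(s["target"]),
            column=s["column"],
            position_1based=s["position_1based"],
            target_state=s["target_state"],
            other_states=frozenset(s["other_states"]),
        )
        for s in d["true_sites"]
    ]
    return SimulationTruth(
        true_sites=sites,
        true_labels=dict(d["true_labels"]),
        mislabeled=set(d["mislabeled"]),
        reference_annotation=ItsAnnotation(
            tuple(ann["its1"]), tuple(ann["r58s"]), tuple(ann["its2"])
        ),
        member_annotations={},
    )


def write_fixture_bundle(
    alignment: LabeledAlignment,
    truth: SimulationTruth,
    metadata: Sequence[SpecimenRecord],
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    overwrite: bool = False,
) -> dict:
    """Write alignment FASTA, truth JSON, metadata CSV and annotation JSON.

    The truth JSON embeds the generating configuration, making the
    bundle self-describing and regenerable.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ConfigError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fasta",
        "truth": out / "truth.json",
        "metadata": out / "specimens.csv",
        "annotation": out / "annotation.json",
    }
    write_labeled_fasta(alignment, paths["alignment"])
    payload = _truth_to_dict(truth)
    if config is not None:
        payload["config"] = config.to_dict()
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths["metadata"].write_text(_records_to_csv(metadata))
    save_annotations(truth.member_annotations, paths["annotation"])
    return {k: str(v) for k, v in paths.items()}


def load_fixture_bundle(
    bundle_dir: str | Path,
) -> tuple[LabeledAlignment, SimulationTruth, SimulationConfig | None]:
    """Reload a bundle written by :func:`write_fixture_bundle`."""
    from .seq_io_annotation import load_annotations, read_labeled_fasta

    out = Path(bundle_dir)
    alignment = read_labeled_fasta(out / "alignment.fasta")
    payload = json.loads((out / "truth.json").read_text())
    truth = _truth_from_dict(payload)
    truth.member_annotations = load_annotations(out / "annotation.json")
    config = None
    if "config" in payload:
        config = SimulationConfig.from_dict(payload["config"])
        mask = np.ones(config.total_length, dtype=bool)
        s, e = config.region_bounds()["r58s"]
        mask[s:e] = False
        alignment = LabeledAlignment(alignment.members, mask)
    return alignment, truth, config
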