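#!/usr/bin/env python
"""Optional reproduction against the real GenBank ITS sequences.

This script is NOT part of the test suite: it needs network access to
NCBI and an external aligner.  It downloads the study's ITS accession
collection (the published per-species GenBank lists plus the study's own
depositions MN811165.1-MN811200.1 and the annotated Arabidopsis thaliana
reference X52320.1), aligns the set with MAFFT, transfers the ITS
annotation, masks the 5.8S block, calls diagnostic sites and builds the
bootstrapped NJ tree with a misassignment report.

Expected qualitative outcome: diagnostic sites for 8 of the 12 species
(66.6%), including a single site for P. paradoxa and a deletion-state
site for P. coerulescens; P. lemmonii and P. angusta without sites; the
P. brachystachys / P. canariensis pair indistinguishable; and several
misassigned accessions flagged (e.g. a P. angusta-labeled sequence
resolving inside the P. aquatica clade).  Exact site positions depend on
the alignment produced, so they are reported, not asserted.

Usage::

    python scripts/genbank_reproduction.py --email you@example.org \
        --out scratch/genbank_run/
"""

from __future__ import annotations

import argparse
import subprocess
import sys
from pathlib import Path

ACCESSIONS = {
    "Phalaris angusta": ["KX873129.1", "KF753774.1", "JF951055.1",
                         "MN811165.1", "MN811166.1", "MN811167.1",
                         "MN811168.1", "MN811169.1"],
    "Phalaris aquatica": ["KU883516.1", "KF753775.1", "JF951056.1", "KF753776.1",
                          "KC512901.1", "JF951076.1", "KX873130.1",
                          "MN811170.1", "MN811171.1", "MN811172.1",
                          "MN811173.1", "MN811177.1"],
    "Phalaris arundinacea": ["KF753779.1", "JF951077.1", "KF713257.1",
                             "FJ766174.1", "KF713256.1", "KU883517.1",
                             "KF713255.1", "HQ600518.1", "KP711073.1",
                             "KF713254.1", "KF713253.1", "FJ821785.1",
                             "KF713251.1", "HF564628.1", "KF713250.1",
                             "KF753778.1", "MN811174.1", "MN811175.1",
                             "MN811176.1", "MN811200.1"],
    "Phalaris brachystachys": ["KC512902.1", "KF753780.1", "JF951057.1",
                               "MN811178.1", "MN811179.1", "MN811180.1",
                               "MN811181.1"],
    "Phalaris californica": ["JF951078.1", "JF951064.1", "KF753781.1",
                             "MN811182.1"],
    "Phalaris canariensis": ["KX147547.1", "DQ539580.1", "FJ178782.1",
                             "JF951058.1", "KX147537.1", "KP296086.1",
                             "MN811183.1", "MN811184.1", "MN811185.1"],
    "Phalaris caroliniana": ["JF951065.1", "JF951080.1", "JF951079.1",
                             "MN811186.1", "MN811187.1", "MN811188.1"],
    "Phalaris coerulescens": ["JF951081.1", "JF951066.1", "DQ539581.1",
                              "KC512900.1", "HE802172.1", "KF753782.1",
                              "MN811189.1", "MN811190.1"],
    "Phalaris lemmonii": ["MF964010.1", "JF951082.1", "MN811191.1",
                          "MN811192.1"],
    "Phalaris minor": ["JF907187.1", "JF951084.1", "JF951069.1", "KX873131.1",
                       "KU883518.1", "JF951086.1", "MN811193.1"],
    "Phalaris paradoxa": ["JF951070.1", "JF951071.1", "KX873133.1",
                          "KX873132.1", "JF951088.1", "KF753783.1",
                          "JF951089.1", "KC512899.1", "MN811194.1",
                          "MN811195.1"],
    "Phalaris truncata": ["L36522.1", "KC512903.1", "JF951059.1",
                          "MN811196.1", "MN811197.1", "MN811198.1",
                          "MN811199.1"],
}
REFERENCE = "X52320.1"  # annotated Arabidopsis thaliana ITS region


def fetch(email: str, out_dir: Path) -> Path:
    from Bio import Entrez, SeqIO

    Entrez.email = email
    raw = out_dir / "raw.fasta"
    ids = [a for accs in ACCESSIONS.values() for a in accs] + [REFERENCE]
    with Entrez.efetch(db="nucleotide", id=",".join(ids), rettype="fasta",
                       retmode="text") as handle, raw.open("w") as out:
        out.write(handle.read())
    species_of = {a: sp for sp, accs in ACCESSIONS.items() for a in accs}
    species_of[REFERENCE] = "Arabidopsis thaliana"
    labeled = out_dir / "labeled.fasta"
    with labeled.open("w") as out:
        for rec in SeqIO.parse(str(raw), "fasta"):
            acc = rec.id
            out.write(f">{acc}|{species_of.get(acc, 'unknown')}\n{rec.seq}\n")
    return labeled


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="NCBI Entrez contact")
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--seed", type=int, default=17)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    labeled = fetch(args.email, args.out)
    aligned = args.out / "aligned.fasta"
    with aligned.open("w") as out:
        subprocess.run(["mafft", "--auto", str(labeled)], stdout=out, check=True)

    from herbita.diagnostic_barcode import find_diagnostic_sites, write_barcode_table
    from herbita.distance_tree import (bootstrap_support, flag_misassignments,
                                       write_newick)
    from herbita.seq_io_annotation import (ItsAnnotation, mask_58s,
                                           read_labeled_fasta,
                                           transfer_annotation)

    aln = read_labeled_fasta(aligned)
    members = [m for m in aln.members if m.species != "Arabidopsis thaliana"]
    ref = next(m for m in aln.members if m.species == "Arabidopsis thaliana")
    # X52320.1 ITS1/5.8S/ITS2 intervals on the ungapped reference must be
    # supplied here (GenBank feature table of X52320.1); edit as needed.
    ref_annotation = ItsAnnotation((0, 271), (271, 435), (435, 625))
    from herbita.seq_io_annotation import LabeledAlignment

    annotations = {
        m.accession: transfer_annotation(ref, ref_annotation, m)
        for m in members
    }
    study = LabeledAlignment(members)
    masked = mask_58s(study, annotations)
    pair = ("Phalaris brachystachys", "Phalaris canariensis")
    table = find_diagnostic_sites(
        masked, targets=[{sp} for sp in masked.species] + [pair]
    )
    write_barcode_table(table, args.out / "barcode.tsv")
    with_sites = {next(iter(s.target)) for s in table.sites if len(s.target) == 1}
    print(f"species with diagnostic sites: {len(with_sites)}/12")
    print(f"without: {sorted(table.species_without)}")
    print(f"indistinguishable: {table.indistinguishable_groups}")
    tree = bootstrap_support(masked, replicates=100, seed=args.seed)
    write_newick(tree, args.out / "tree.nwk")
    report = flag_misassignments(tree)
    for acc, labeled_sp, resolved in report.flagged:
        print(f"flagged {acc}: labeled {labeled_sp}, resolves near {resolved}")


if __name__ == "__main__":
    main()
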