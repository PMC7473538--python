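"""Reading a MaxQuant proteinGroups table and a FASTA length database.

Writes a tiny synthetic proteinGroups.txt-style file (decoy and
contaminant rows included) plus a matching FASTA, reads them back, and
shows the filtering and the NSAF-ready lengths.
"""

import tempfile
from pathlib import Path

import spcnorm as sp

workdir = Path(tempfile.mkdtemp())

# synthetic stand-in for a MaxQuant proteinGroups.txt (not real search output)
pg = workdir / "proteinGroups.txt"
pg.write_text(
    "Majority protein IDs\tSequence length\tMS/MS count A1\tMS/MS count A2\t"
    "Reverse\tPotential contaminant\n"
    "P00924;P00925\t436\t40\t38\t\t\n"
    "P00330\t348\t25\t27\t\t\n"
    "REV__P99999\t120\t3\t1\t+\t\n"
    "CON__P02769\t607\t12\t14\t\t+\n"
    "P0A6F5\t548\t9\t0\t\t\n"
)
fasta = workdir / "db.fasta"
fasta.write_text(
    ">sp|P00924|ENO1_YEAST Enolase 1\n" + "M" * 436 + "\n"
    ">sp|P00330|ADH1_YEAST Alcohol dehydrogenase 1\n" + "M" * 348 + "\n"
    ">sp|P0A6F5|CH60_ECOLI 60 kDa chaperonin\n" + "M" * 548 + "\n"
)

m = sp.read_count_table(
    pg,
    dialect="maxquant_proteingroups",
    metadata={"A1": {"condition": "A", "pair": "A"},
              "A2": {"condition": "A", "pair": "A"}},
    lengths=sp.lengths_from_fasta(fasta),
)
print(f"kept {m.n_proteins} proteins after decoy/contaminant filtering "
      f"(from 5 rows):")
print(m.counts)
print("\nlengths for NSAF (from the FASTA, keyed by leading accession):")
print(m.lengths)
print("\nNSAF values (each run sums to 1):")
print(sp.normalize(m, "nsaf").values.round(4))
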