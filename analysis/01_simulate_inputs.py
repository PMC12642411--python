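#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Produces a genome with a planted full-length endogenous-retrovirus insertion
(TSD "TAGTTA", paired identical LTRs, three long ORFs), a population haplotype
sample in which the insertion arose 2,000 generations ago, a 260-individual
case/control genotype matrix with one dominant causal locus, and a CpG
methylation track with hypomethylated LTRs. Everything downstream reads these
files from results/data/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ervpop.core import Demography
from ervpop import io
from ervpop.synthetic_data import (
    default_construct,
    make_case_control,
    make_erv_genome,
    make_methylation_track,
    simulate_population,
)

SEED = 20_260
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# --- planted genome -------------------------------------------------------
construct = default_construct(SEED)
genome, element = make_erv_genome(
    40_000, construct, 17_000, seed=SEED + 1, target_site="TAGTTA"
)
io.write_fasta({"synthetic_genome": genome}, OUT / "genome.fa")
io.write_bed(io.element_to_bed(element), OUT / "element_truth.bed")
io.write_elements_gff3([element], OUT / "element_truth.gff3")
print(f"planted element: {element.start}-{element.end} "
      f"({element.length} bp), TSD={element.tsd}, {len(element.orfs)} ORFs")

# --- population sample ----------------------------------------------------
demography = Demography.constant(1000)
io.write_demography(demography, OUT / "demography.json")
hapset, truth = simulate_population(
    demography, 2000, 1e-8, 50_000, 1000, 22, seed=SEED + 2, n_carriers=11
)
io.write_hapset(hapset, OUT / "haplotypes.fa", OUT / "haplotype_labels.tsv")
print(f"population sample: {sum(truth.carrier_flags)} carriers / "
      f"{len(hapset.names)} haplotypes, insertion frequency "
      f"{truth.allele_frequency:.3f}, {truth.mutation_positions.size} "
      "carrier-lineage mutations")

# --- case/control genotypes ----------------------------------------------
genotypes, phenotypes = make_case_control(260, 2000, 1000, 0.1363, seed=SEED + 3)
io.write_vcf(genotypes, OUT / "genotypes.vcf", contig_length=2001)
pd.DataFrame(
    {"individual": [f"ind_{i}" for i in range(260)], "phenotype": phenotypes}
).to_csv(OUT / "phenotypes.tsv", sep="\t", index=False)
print(f"case/control: {int(phenotypes.sum())} cases / 260 individuals, "
      "causal site index 1000 (dominant, fully penetrant)")

# --- methylation track ----------------------------------------------------
track, labels = make_methylation_track(600, element, seed=SEED + 4)
io.write_methylation_tsv(track, OUT / "methylation.tsv")
print(f"methylation: {len(track)} CpGs "
      f"({(labels == 'ltr').sum()} in LTRs, {(labels == 'body').sum()} in body)")
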