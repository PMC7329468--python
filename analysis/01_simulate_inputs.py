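#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes a 500 kb nuclear genome carrying 20 planted mitochondrial fragments
plus two verbatim contaminant contigs, the organellar query genome with its
feature annotation, a 60-tip Yule tree with Brownian traits (lambda 0.8),
and a 24-pair lineage design, all under scratch/data/ (bulky, regenerable
inputs; the small derived tables land under results/).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from norgscan.seq_io import (
    GenomeAssembly,
    SequenceRecord,
    write_fasta,
    write_gff_features,
)
from norgscan.synthetic import (
    SimulationConfig,
    TraitSimConfig,
    make_contaminant_contigs,
    make_paired_design,
    plant_insertions,
    random_sequence,
    simulate_organelle,
    simulate_traits,
    simulate_tree,
)

SEED = 20240917
OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # detection inputs (organelle and background on separate rng streams)
    org = simulate_organelle(16_000, gc=0.45, seed=SEED + 10, n_features=12)
    bg = SequenceRecord("chr1", random_sequence(500_000, 0.41, rng))
    cfg = SimulationConfig(nuclear_size=500_000, n_insertions=20,
                           insertion_min_len=200, insertion_max_len=2_000,
                           seed=SEED + 1)
    asm, truth = plant_insertions(bg, org, cfg)
    contams = make_contaminant_contigs(org, (3_000, 6_000), seed=SEED + 2)
    asm = GenomeAssembly(asm.species, list(asm.records) + contams, "scaffold")
    write_fasta(asm.records, OUT / "nuclear.fasta")
    write_fasta([org.record], OUT / "mitochondrion.fasta")
    write_gff_features(org.features, org.record.id, OUT / "mitochondrion.gff3")
    pd.DataFrame([t.__dict__ for t in truth]).to_csv(
        OUT / "insertion_truth.tsv", sep="\t", index=False
    )
    pd.DataFrame({"contig": [c.id for c in contams]}).to_csv(
        OUT / "contamination_truth.tsv", sep="\t", index=False
    )
    print(f"detection: {len(truth)} insertions "
          f"({min(t.length for t in truth)}-{max(t.length for t in truth)} bp, "
          f"identity {min(t.realized_identity_pct for t in truth):.1f}-"
          f"{max(t.realized_identity_pct for t in truth):.1f}%), "
          f"{len(contams)} contaminant contigs -> {OUT}")

    # comparative inputs: tree + traits
    tree = simulate_tree(60, seed=SEED + 3)
    tree.write(path=str(OUT / "tree.nwk"), schema="newick")
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    levels = rng.choice(["contig", "scaffold", "chromosome", "complete"],
                        size=len(tips), p=[0.3, 0.4, 0.2, 0.1])
    # traits follow the coded assembly level with a phylogenetic residual
    codes = np.where(levels == "contig", 1.0, 2.0)
    cfg_t = TraitSimConfig(tree, lambda_pagel_true=0.8, slope_true=1.5,
                           sigma2=1.0, predictor=codes, seed=SEED + 4)
    y = simulate_traits(cfg_t)
    pd.DataFrame({"species": tips, "assembly_level": levels,
                  "predictor": codes, "trait": y}).to_csv(
        OUT / "traits.tsv", sep="\t", index=False
    )
    print(f"comparative: 60-tip tree, traits with lambda=0.8, slope=1.5 "
          f"on assembly-level codes")

    # paired lineage design (null)
    pairs = make_paired_design(24, effect_delta=0.0, seed=SEED + 5)
    pairs["group"] = (["invertebrate"] * 9 + ["plant"] * 12 + ["fungus"] * 3)
    pairs.to_csv(OUT / "paired_design.tsv", sep="\t", index=False)
    print("paired design: 24 lineage pairs under the null")
    return 0


if __name__ == "__main__":
    sys.exit(main())
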