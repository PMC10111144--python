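#!/usr/bin/env python
"""Generate the synthetic study corpus.

Emits, under results/synthetic/: a proteome FASTA with planted poly-S
tracts (prevalence 0.37, the transcript-level rate of compositional bias
in the filtered human genome set), a gene-disease association table with a
planted odds ratio of 1.8 between tract presence and disease, a tabular
homology hit table realizing a random planted profile over 8 named
proteomes, and the ground truth as JSON lines.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from compbias.sequence_io import write_fasta
from compbias.synthetic_data import (
    SyntheticSpec,
    TractSpec,
    generate_disease_labels,
    generate_hit_table,
    generate_proteome,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20220404


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(
        n_proteins=2000,
        length_range=(80, 400),
        tracts=(TractSpec("S", 14, purity=1.0, probability=0.37),),
        baseline_disease_probability=0.03,
        odds_ratio=1.8,
        seed=SEED,
    )
    records, truth = generate_proteome(spec)
    rows = generate_disease_labels(truth, spec)
    write_fasta(records, OUT / "proteins.fasta")
    pd.DataFrame(rows, columns=["gene_id", "doid", "disease_name"]).to_csv(
        OUT / "associations.tsv", sep="\t", index=False
    )

    rng = np.random.default_rng(SEED)
    proteomes = [f"UP{i + 1:09d}-{i + 1:08d}" for i in range(8)]
    queries = [p.protein_id for p in truth.proteins[:12]]
    presence = rng.integers(0, 3, size=(len(queries), len(proteomes)))
    hit_rows, _ = generate_hit_table(
        presence, queries, proteomes, seed=SEED, noise_rate=0.3
    )
    (OUT / "hits.tsv").write_text("\n".join(hit_rows) + "\n")
    np.savetxt(OUT / "planted_profile.tsv", presence, fmt="%d", delimiter="\t")

    with open(OUT / "truth.jsonl", "w") as fh:
        for protein in truth.proteins:
            fh.write(json.dumps({
                "protein_id": protein.protein_id,
                "tracts": [
                    {"residue": t.residue, "start": t.start, "end": t.end}
                    for t in protein.tracts
                ],
                "disease": protein.disease,
            }) + "\n")

    n_tract = sum(1 for p in truth.proteins if p.has_tract)
    n_disease = sum(1 for p in truth.proteins if p.disease)
    print(f"wrote {len(records)} proteins ({n_tract} with planted tracts, "
          f"{n_disease} disease-labelled), {len(hit_rows)} hit rows -> {OUT}")


if __name__ == "__main__":
    main()
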