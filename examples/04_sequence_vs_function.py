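"""End-to-end synthetic study: does sequence divergence predict function?

Simulates 12 ortholog pairs whose screen-profile divergence is driven by
protein (amino-acid) divergence, writes the FASTA and plate files, runs the
full pipeline, and prints the Spearman correlation of each sequence metric
with the functional distance 1 - R.
"""

import tempfile
from pathlib import Path

from orfunc import StudySimConfig, simulate_study
from orfunc import io as oio
from orfunc import pipeline

study = simulate_study(StudySimConfig(n_sets=12, seed=42))

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    seqs = {}
    for sim in study.pairs:
        seqs[sim.pair.id_a] = sim.pair.nt_a
        seqs[sim.pair.id_b] = sim.pair.nt_b
    oio.write_fasta(tmp / "seqs.fasta", seqs)
    oio.write_plate_csv(tmp / "plate.csv", study.plate)
    pairs = list(zip(study.pair_table["id_a"], study.pair_table["id_b"]))
    _, pair_table, corr = pipeline.run_all(tmp / "seqs.fasta", pairs,
                                           tmp / "plate.csv", tmp / "out")

print(f"{int(pair_table['included'].sum())} of {len(pair_table)} pairs pass "
      "the responsiveness filter (>= 3 responsive odors per member)\n")
print("Spearman correlation with functional distance (1 - R):")
for _, row in corr.iterrows():
    print(f"  {row['metric']:13s}: r_s = {row['r_s']:+.2f}  (p = {row['p']:.3g})")
print("\n-> the amino-acid (Grantham) metric tracks functional divergence"
      " most closely, as configured: the generator couples profile"
      " perturbation to nonsynonymous changes only")
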