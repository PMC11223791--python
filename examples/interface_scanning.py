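"""Alanine scanning and saturation mutagenesis over an interface.

Trains a small model on synthetic data, then scans every interface residue
of one complex: X->A for the alanine scan (alanines skipped, glycines
included), all 19 substitutions for saturation.  Also enumerates all double
mutants on one side of the interface and prints the extremes.
"""

import ppiddg as pg
from ppiddg.model import ModelConfig, alanine_scan, enumerate_multi, saturation_scan, train
from ppiddg.pipeline import FeaturePipeline

records, structures = pg.generate_synthetic_dataset(
    80, pg.SyntheticGroundTruth(seed=2))
pipeline = FeaturePipeline(provider=pg.stub_embedding_provider(16, seed=0))
state = train(ModelConfig(seed=0, epochs=20),
              pipeline.featurize_dataset(records, structures))

structure = structures[sorted(structures)[0]]
print(f"interface: {len(pg.interface_residues(structure))} residues")

ala = alanine_scan(state, structure, pipeline)
print(f"\nalanine scan ({len(ala)} substitutions):")
print(ala.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))

sat = saturation_scan(state, structure, pipeline)
best = sat.nlargest(3, "predicted_ddg")
worst = sat.nsmallest(3, "predicted_ddg")
print(f"\nsaturation mutagenesis: {len(sat)} predictions "
      f"(19 per interface residue)")
print("most binding-enhancing:")
print(best.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))
print("most destabilizing:")
print(worst.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))

inc, dec = enumerate_multi(state, structure, pipeline, side={"A"},
                           order=2, top_k=5)
print(f"\ntop double mutants on chain A (of {19 * 19} substitution pairs "
      "per position pair, ranked additively):")
print(inc.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))
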