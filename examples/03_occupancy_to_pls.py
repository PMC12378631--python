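"""From occupancy fingerprints to ranked contact importances via PLS.

Generates the full planted SAR dataset (8 ligands x 3 replicates), builds
the ligands x contacts occupancy matrix, fits the PLS model of pIC50 on
occupancies, and prints the standardized coefficients next to the planted
ground truth: the ARG929-like salt bridge was planted to *lower* potency,
the ARG439-like one to enhance it.
"""

import numpy as np

from contactsar import contact_weights
from contactsar import synthetic as syn
from contactsar.pipeline import analyze_trajectories

spec = syn.default_spec(seed=1)
dataset = syn.generate_sar_dataset(spec)
pic50_by_ligand = dict(zip(spec.ligand_ids, dataset.pic50))

matrix, model = analyze_trajectories(
    dataset.topology, dataset.trajectories, pic50_by_ligand
)

print("occupancy matrix (mean over replicates, %):")
print(matrix.to_dataframe().round(1).to_string(index=False))
print()

planted = {
    {"salt_bridge": f"C_COOH-{p.residue_label}:CZ",
     "pi_stack": f"ring-{p.residue_label}:ring"}[p.kind]: p.beta_true
    for p in spec.programs
}
print(f"{'contact':<22} {'beta_std':>9} {'planted beta':>13}")
order = np.argsort(-np.abs(model.beta_standardized))
for i in order:
    cid = model.contact_ids[i]
    truth = planted.get(cid, 0.0)
    print(f"{cid:<22} {model.beta_standardized[i]:>9.3f} {truth:>13.1f}")

print()
print("first-component weights, C-terminal carboxylate contacts only:")
for cid, w in contact_weights(model, component=1, ligand_part="C_COOH"):
    print(f"  {cid:<22} {w:+.3f}")
print()
print("A negative coefficient means a contact whose persistence tracks lower")
print("potency (the ARG929-like pattern); a positive one tracks enhanced")
print("activity (ARG439-like).  Zero-variance control contacts get weight 0.")
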