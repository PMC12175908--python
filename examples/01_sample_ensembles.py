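"""Generate synthetic apo and receptor-bound ensembles and measure compaction.

The apo sampler produces self-avoiding persistent chains whose mean radius of
gyration falls in the 52-59 Å range expected for a 311-residue disordered
domain with partial helical motifs; the complex sampler anchors two motifs per
state on the receptor proxy, compacting the chain to ~35 Å.
"""

import numpy as np

from idpre import ChainSpec, GroundTruth, sample_apo_ensemble, sample_complex_ensemble
from idpre.landscape import radius_of_gyration
from idpre.synthetic import default_states

spec = ChainSpec()  # 311 residues, LD motifs at 3-14 / 144-155 / 263-274

apo = sample_apo_ensemble(spec, n_frames=100, seed=1)
_, apo_stats = radius_of_gyration(apo)
print(f"apo ensemble: {apo.n_frames} frames, "
      f"mean Rg {apo_stats['all']['mean']:.1f} A "
      f"(IQR {apo_stats['all']['q1']:.1f}-{apo_stats['all']['q3']:.1f} A)")

truth = GroundTruth(state_weights={"I": 0.4, "II": 0.3, "III": 0.2, "IV": 0.1},
                    seed=1)
complex_ens = sample_complex_ensemble(spec, default_states(), truth,
                                      n_frames_per_state=50)
rg, stats = radius_of_gyration(complex_ens, weights=complex_ens.true_weights,
                               per_state=True)
print(f"bound complex: {complex_ens.n_frames} frames, "
      f"weighted mean Rg {stats['all']['mean']:.1f} A")
for state in "I II III IV".split():
    w = complex_ens.true_weights[complex_ens.states == state].sum()
    print(f"  state {state}: ground-truth weight {w:.2f}, "
          f"Rg {stats[state]['mean']:.1f} A")

# The ~20 A drop from apo to bound reflects the compaction of the disordered
# chain when two of its helical motifs dock onto opposite receptor faces.
print(f"compaction on binding: {apo_stats['all']['mean'] - stats['all']['mean']:.1f} A")
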