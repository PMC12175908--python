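"""Back-calculate PRE rates and intensity ratios for one spin-label site.

For each frame a pseudo-rotamer cloud of electron positions is placed at the
label site, Boltzmann-weighted by steric clash; the Solomon-Bloembergen
equation turns the r^-6-averaged electron-proton distances and order
parameters into per-residue Gamma2 rates, which map to HSQC intensity ratios.
"""

import numpy as np

from idpre import ChainSpec, GroundTruth, PhysicalConstants
from idpre.pre import SpinLabelSite, gamma2_ensemble, gamma2_to_intensity, site_gamma2_matrix
from idpre.synthetic import default_states, sample_complex_ensemble

const = PhysicalConstants()  # 600 MHz, tau_c 29 ns, tau_i 500 ps, R2red 40/s
print(f"tau_t (combined correlation time): {const.tau_t*1e12:.0f} ps")

truth = GroundTruth(seed=2)
ens = sample_complex_ensemble(ChainSpec(), default_states(), truth,
                              n_frames_per_state=25)

site = SpinLabelSite("B", 1006)  # receptor site on the a2/a3 face
gamma2 = site_gamma2_matrix(ens, site, target_chain="A", constants=const,
                            seed=2)
avg = gamma2_ensemble(gamma2, ens.true_weights)
ratio = gamma2_to_intensity(avg, const)

print(f"site {site.name}: Gamma2 matrix {gamma2.shape} (residues x frames)")
for res in (10, 150, 270):
    print(f"  residue {res:3d}: <Gamma2> {avg[res-1]:8.1f} /s  "
          f"I_ox/I_red {ratio[res-1]:.3f}")
# Residues that approach the label within ~15-25 A relax measurably faster
# (lower ratios) than remote ones - the distance signature BME exploits.
print(f"residues with measurable PRE (ratio < 0.7): "
      f"{int((ratio < 0.7).sum())} of {len(ratio)}")
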