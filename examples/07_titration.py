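"""Fit per-motif dissociation constants from titration intensity decays.

Synthetic I/I0 decays are generated over the 9-point 10-300 uM ligand ladder
at 100 uM observed protein with the quadratic depletion isotherm and 5%
multiplicative noise, then refitted per residue and summarised per motif.
"""

from idpre.synthetic import synthesize_titration
from idpre.titration import fit_kd_table, motif_kd_summary

kd_true = {"LD1": 17.0, "LD2": 7.0, "LD4": 13.0}  # uM
series = synthesize_titration(kd_true, receptor_conc=100.0, noise_sd=0.05,
                              seed=7)
print(f"titration: {series.data['residue'].nunique()} residues x "
      f"{series.data['ligand_conc'].nunique()} ligand concentrations")

fits = fit_kd_table(series)
summary = motif_kd_summary(fits, series.motif_map)
print("per-motif Kd (mean +/- sample SD over residues):")
for _, row in summary.motif_summary.iterrows():
    print(f"  {row['motif']}: {row['kd_mean']:5.1f} +/- {row['kd_sd']:.1f} uM "
          f"({row['n_residues']} residues; true {kd_true[row['motif']]})")
# LD2 binds tightest - the anchor motif of the multistate complex.
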