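"""Small phase diagram over the I_CaL x I_Ks scaling plane.

Classifies a coarse grid of (alpha(P_Ca), alpha(G_Ks)) cells on the
voltage-driven background (alpha(k_max)=2, alpha(J_Caslmyo)=2.64).
Expect normal repolarization at low alpha(P_Ca), EADs in a band, and
repolarization failure at high alpha(P_Ca) / low alpha(G_Ks).
"""
import numpy as np
from eadkit.scans import phase_diagram

grid = phase_diagram(pca_values=np.geomspace(1.0, 12.0, 5),
                     gks_values=np.geomspace(0.6, 2.0, 4),
                     background_alpha=dict(k_max=2, J_Caslmyo=2.64,
                                           I_NCX_bar=1))
short = {"none": ".", "repol_failure": "F", "typeI": "1", "typeII": "2",
         "typeIII": "3", "typeIV": "4", "diverged": "x"}
print("rows: alpha(G_Ks) high->low | cols: alpha(P_Ca) low->high")
for i in range(len(grid.gks_values) - 1, -1, -1):
    row = " ".join(short[grid.labels[i, j]]
                   for j in range(len(grid.pca_values)))
    print(f"  G_Ks x{grid.gks_values[i]:4.2f} | {row}")
print("legend: . normal, F failure, 1-4 EAD mechanism types")
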