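"""Convert published mean Vt values into organ boron-10 concentrations.

Feeds the reported mean MA2 distribution volumes and the mean plasma boron
levels (14.9 ppm at 1 h, 6.1 ppm at 2 h, for the 30 g BPA-fructose dose)
through the activity -> molar -> ppm -> dose-scaling chain.  The printed
organ ppm values are what a treatment planner needs: the expected normal-
tissue boron burden at irradiation time.
"""

from fbpakin import estimate_tissue_boron, therapeutic_multiplier

MA2_VT = {
    "pancreas": 0.94, "liver": 0.81, "salivary_glands": 0.74, "esophagus": 0.69,
    "stomach": 0.61, "heart": 0.59, "bone_marrow": 0.55, "intestines": 0.55,
    "spleen": 0.53, "brain": 0.39, "lung": 0.16,
}
PLASMA_PPM = {60.0: 14.9, 120.0: 6.1}

print(f"dose-scaling multiplier H/B = {therapeutic_multiplier():.1f}\n")
print(f"{'organ':16s} {'1 h ppm':>8s} {'2 h ppm':>8s}")
for organ, vt in MA2_VT.items():
    row = [
        estimate_tissue_boron(vt, PLASMA_PPM[t], t, voi_name=organ).therapeutic_ppm
        for t in (60.0, 120.0)
    ]
    print(f"{organ:16s} {row[0]:8.1f} {row[1]:8.1f}")
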