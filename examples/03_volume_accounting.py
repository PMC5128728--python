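"""The volume-accounting arithmetic, end to end.

Given a prophase chromatin complement of 109.8 um^3 with mean chromosome
diameter 0.64 um, a nucleolus of 54.4 um^3, and a metaphase complement of
175.9 um^3 with summed surfaces 1175 -> 899 um^2, derive the packing
density, the prophase+nucleolus sum, the metaphase volume excess, the
surface reduction, and the uniform-shell thickness that would hold the
nucleolar volume on the prophase complement.
"""

from chromovol import accounting

V_PRO, V_NUC, V_MET = 109.8, 54.4, 175.9
D_PRO = 0.64
S_PRO, S_MET = 1175.0, 899.0
GENOME_MB = 12344.0  # 4C female diploid complement

rho = accounting.packing_density(GENOME_MB, V_PRO)
print(f"packing density: {GENOME_MB:.0f} Mb / {V_PRO} um^3 = {rho:.1f} Mb/um^3")

acct = accounting.volume_accounting(V_PRO, V_NUC, V_MET)
print(f"prophase + nucleolus: {acct['prophase_plus_nucleolus_um3']:.1f} um^3")
print(f"metaphase excess over prophase: {acct['metaphase_vs_prophase_pct']:.0f}% "
      f"({acct['metaphase_vs_prophase_base']} base)")
print(f"metaphase vs the sum: {acct['metaphase_vs_sum_pct']:.1f}% "
      f"(gap {acct['gap_um3']:.1f} um^3)")

print(f"surface reduction: {accounting.surface_reduction(S_PRO, S_MET):.0f}%")

t_nm = accounting.shell_thickness_from_volume(V_PRO, D_PRO, V_NUC)
print(f"shell thickness holding the nucleolar volume: {t_nm:.1f} nm "
      f"(~{round(t_nm / 10) * 10} nm)")

frac = accounting.periphery_fraction(D_PRO, round(t_nm / 10) * 10)
print(f"periphery fraction of a {D_PRO} um cylinder with that shell: {frac:.1%}")
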