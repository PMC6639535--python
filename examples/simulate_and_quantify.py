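"""Full virtual phantom study: simulate, correct, fit, cluster, quantify.

Runs the complete chain at a reduced 64 x 64 matrix: seven-bottle digital
phantom, field-cycling spin-echo acquisition with per-line phase instability
and noise (voxel SNR ~ 100), empty-region ghost correction, voxel-wise T1
maps at six evolution fields, dispersion-feature clustering (BSA vs MnCl2)
and concentration estimation against the 0.74 mM / 20 % w/w references.
"""

from ffcmri.pipeline import run_phantom_experiment

res = run_phantom_experiment(seed=42, matrix=64, n_evolution_times=6, snr=100.0)

e_before, e_after = res.kspace_ghost_energy
print(f"ghost energy in empty region: {e_before:.1f} -> {e_after:.1f} after correction\n")

print(f"{'bottle':>6} {'material':>9} {'c true':>8} {'c est':>8} {'err %':>6}")
for lab in sorted(res.true_concentration):
    c_t, c_e = res.true_concentration[lab], res.bottle_concentration[lab]
    print(f"{lab:>6} {res.bottle_material[lab]:>9} {c_t:>8.2f} {c_e:>8.2f} "
          f"{100*abs(c_e-c_t)/c_t:>6.1f}")

errs = [abs(res.bottle_concentration[l] - res.true_concentration[l]) / res.true_concentration[l]
        for l in res.true_concentration]
print(f"\nmax concentration error: {100*max(errs):.1f}% "
      "(bottles 1-4 in mM MnCl2, 5-7 in % w/w BSA)")
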