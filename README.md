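# ffcmri

A virtual **fast field-cycling (FFC) MRI** scanner and T1-dispersion
quantification toolkit.

FFC-MRI switches the main magnetic field B0 *during* the pulse sequence:
magnetisation is built at a high polarisation field, left to relax at a
selectable **evolution field** anywhere between ~50 µT and 0.2 T, and read
out at a fixed detection field. Because the longitudinal relaxation rate
R1 = 1/T1 depends on field — the **NMRD profile** R1(B0) — this gives access
to molecular-dynamics contrast that fixed-field MRI cannot see, including
the quadrupolar cross-relaxation peaks of immobilised proteins near 60 mT
(proton Larmor frequency f = (γ/2π)·B0 with γ/2π = 42.578 MHz/T).

Running a resistive, fast-switching whole-body magnet brings its own
problems: ramp-rate and duty-cycle limits, mains-harmonic field ripple,
slow thermal drift, and line-to-line phase instability that ghosts the
images. This package simulates all of it and implements the full software
chain a real scanner of this kind needs:

- **`ffcmri.dispersion`** — parametric NMRD models (power law
  `1/T1 = a·f_L^b`, Lorentzian dispersion, quadrupolar peak sets) with
  linear concentration scaling, plus the seven-bottle phantom reference
  library (MnCl2 at 0.38/0.52/0.74/1.00 mM, cross-linked BSA at
  5/10/20 % w/w).
- **`ffcmri.fieldcycle`** — field waveforms under slew (12 T/s operational,
  20 T/s ceiling) and 50 % power-duty constraints; longitudinal Bloch
  propagation dMz/dt = (m0(B(t)) − Mz)/T1(B(t)) through arbitrary B0(t).
- **`ffcmri.scanner`** — digital phantoms, field-cycling spin-echo k-space
  acquisition with instability artefacts, reconstruction, empty-region
  ghost-phase correction, navigator-FID field estimation, closed-loop drift
  correction quantised to the 16-bit DAC (3 µT ≙ 130 Hz), the FID-phase
  field-stability metric (ppm), and Rician-corrected SNR
  (factor √(2−π/2) = 0.655).
- **`ffcmri.quantify`** — inversion-recovery T1 fitting, NMRD assembly,
  power-law dispersion mapping (the *b* exponent image), dispersion-feature
  extraction (span, dispersion at 20 mT, quadrupolar amplitude), k-means
  material clustering, SSR-based classification and concentration
  estimation from the dispersion offset against a known reference.
- **`ffcmri.shim`** — teacher-learner (TLBO) shim optimisation maximising
  the post-saturation FID amplitude (6 learners, ≤50 iterations).
- **`ffcmri.cli` / `ffcmri.config`** — the `ffc` command line
  (simulate/quantify/shim/stability/demo/report), YAML run configurations
  and HDF5/NIfTI/CSV serialisation.

## Worked example

`examples/simulate_and_quantify.py` runs the whole chain on a 64×64
seven-bottle phantom — FCSE acquisition at 6 evolution fields × 6 evolution
times with per-line phase errors (σ = 0.1 rad) and voxel SNR ≈ 100, ghost
correction, voxel-wise T1 maps, clustering and concentration estimation:

```
ghost energy in empty region: 22.6 -> 16.4 after correction

bottle  material   c true    c est  err %
     1     MnCl2     0.38     0.38    0.9
     2     MnCl2     0.52     0.52    0.1
     3     MnCl2     0.74     0.75    1.0
     4     MnCl2     1.00     1.00    0.1
     5       BSA     5.00     5.08    1.5
     6       BSA    10.00    10.00    0.0
     7       BSA    20.00    20.07    0.3

max concentration error: 1.5% (bottles 1-4 in mM MnCl2, 5-7 in % w/w BSA)
```

Every bottle is assigned the right material family from its dispersion
features alone, and the estimated concentrations — read off as the vertical
offset of each dispersion curve against the 0.74 mM MnCl2 / 20 % BSA
reference — land within a few percent of truth. The other example scripts
demonstrate the dispersion library, bulk (non-imaging) relaxometry, the
calibration machinery and TLBO shimming; each prints a short, annotated
result. The same pipeline is available from the shell:

```bash
ffc demo --seed 42 --out demo_out     # end-to-end run with manifest
ffc simulate --seed 42 --out run1.h5  # raw k-space + navigators (HDF5)
ffc quantify --seed 42 --out maps     # T1/b-exponent/label maps + tables
ffc shim --seed 1 --out currents.json
```

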