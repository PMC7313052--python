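# sercakit

Structural-state analysis of the SERCA Ca²⁺-ATPase crystal corpus.

SERCA (sarcoendoplasmic reticulum Ca²⁺-ATPase) is a P-type ion pump whose
catalytic cycle (Post–Albers scheme, E1 → E1~P → E2P → E2 → E1) is sampled
by more than seventy crystal structures deposited in the PDB. `sercakit`
turns that corpus into quantitative state assignments and per-state
geometry:

- **Catalytic-state clustering.** All-vs-all backbone (N, Cα, C, O) RMSD
  over the ensemble-common residue set, each pair superposed by Kabsch's
  least-squares rotation; single-linkage clustering at a 0.23 nm cutoff
  (connected components of the thresholded distance graph) yields the
  C1–C6 catalytic-state clusters, anchored so the cluster containing the
  E1·2Ca²⁺ reference (PDB 2c9m) is C1. Structures in singleton components
  can be reported as *unassigned* rather than forced into a cluster.
- **Headpiece kinematics.** After superposing every structure on the rigid
  TM7–TM10 luminal anchor of the reference, each cytosolic domain —
  actuator A (residues 1–40, 115–241), nucleotide-binding N (357–602),
  phosphorylation P (300–356, 603–738) — is Kabsch-fitted from reference to
  target. The rotation operator R gives the domain rotation angle
  θ = arccos((tr R − 1)/2), its axis, and a clockwise/counterclockwise
  sense relative to the membrane normal viewed from the cytosol; the
  centre-of-geometry (COG) shift gives the displacement distance. Also
  computed: A–N / A–P / N–P COG distances and the Met1–Asn510 Cα distance,
  a structural proxy for intramolecular FRET.
- **TM helix geometry.** Helicity fractions from a minimal Kabsch–Sander
  hydrogen-bond assignment (E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332
  kcal/mol, bond if E < −0.5, H for consecutive i→i+4 turns); bending
  angles from bottom/middle/top four-residue section centroids; tilt angles
  against the membrane normal folded into [0°, 90°]; directed interhelical
  (crossing) angles in [0°, 180°].
- **Synthetic generators.** Ideal and kinked poly-alanine helices and toy
  multi-domain "pumps" with analytically known rotations, displacements,
  bends, tilts, and crossing angles, so every operation is testable without
  downloading a single structure.

The estimators follow scikit-learn conventions (`fit` / `transform` /
`fit_predict`, `get_params`, fitted attributes with a trailing underscore)
and return pandas DataFrames; the underlying operations are also exposed as
plain functions.

## Worked example

```python
import sercakit as sk
from sercakit.synthetic import ToyPumpSpec, make_toy_pump

ref, moved, truth = make_toy_pump(ToyPumpSpec())
aligned = sk.anchor_align(moved, ref, truth["domains"]["anchor"])
for name in ("A", "N", "P"):
    t = sk.domain_transform(aligned, ref, truth["domains"][name])
    print(f"{name}: {t.rotation_angle:6.2f} deg {t.sense:16s} "
          f"displacement {t.displacement:5.2f} A")
```

prints

```
A: 110.00 deg counterclockwise displacement 27.37 A
N:  65.00 deg clockwise        displacement 25.00 A
P:  20.00 deg counterclockwise displacement  7.81 A
```

— the toy pump's A block was built with a 110° rotation and an
(18, 20, 5) Å translation (|t| = 27.37 Å), the N block with a 65° turn
about −z (hence *clockwise* seen from the cytosol) and a 25 Å shift, and
the P block with a 20° turn and a 7.81 Å shift; the kinematics recover all
of them from coordinates alone. The magnitudes mirror what the crystal
corpus shows for the E1→E2 transition: large A-domain rotation, tens of
Ångströms of headpiece motion.

Running the full pipeline over a directory of structures:

```bash
sercakit run --config config.yaml      # manifest -> cluster -> kinematics -> TM tables
sercakit cluster structures/ --cutoff-nm 0.23
sercakit synth pump toy/               # generators with ground-truth side files
```

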