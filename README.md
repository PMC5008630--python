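# sfps — selectivity-filter pore simulator

`sfps` is a coarse-grained modelling and analysis toolkit for studying
Na⁺/K⁺ selectivity at the constriction site of voltage-gated sodium
(Na_v) channel pore models.  Mammalian Na_v channels select Na⁺ over K⁺
at a selectivity filter carrying the DEKA motif (Asp–Glu–Lys–Ala, one
residue per pseudo-subunit); mutating the Lys to Arg (DERA) abolishes
selectivity.  `sfps` builds bead-level models of a four-fold pore with a
DEKA/DERA-style inner ring, an acidic outer ring, mobile water beads and
permeant cations, samples them with overdamped Langevin (Brownian)
dynamics, and runs the full analysis chain used to dissect the mechanism:

* **State classification** — a linear SVM separates open and closed
  filter conformations in the plane of the side-chain reporter's radial
  (R) and axial (Z) offsets from the filter center, with per-class 95%
  confidence regions.
* **Binding analysis** — binding-site occupancies along the pore axis
  (Ion_EX, Site_HFS, Site_OC, Site_CEN, Site_INT, Site_IN), 2-D free-energy
  maps by Boltzmann inversion, *G*(R,Z) = −kT·ln[ρ(R,Z)/ρ_max], permeation
  events, and hierarchical clustering of the cation binding modes at the
  outer constriction site (Site_OC).
* **Interaction analysis** — hydrogen-bond occupancies (heavy-atom
  distance criterion), coordination-shell counts with ion-specific
  cutoffs (2.69 Å for Na⁺, 3.22 Å for K⁺, the means of quantum-chemical
  coordinating ranges), and Lys/Arg repulsion-versus-distance profiles.
* **Free-energy perturbation** — the relative binding affinity
  ΔΔG(Na⁺→K⁺) = ΔG_bound − ΔG_bulk of a binding mode, from an alchemical
  Lennard-Jones mutation of the ion over stratified λ windows with a
  flat-bottom positional restraint, estimated with BAR (or exponential
  averaging) and aggregated over repeats as mean ± SD.  ΔΔG > 0 means
  the site prefers Na⁺.

## Worked example

```python
import numpy as np
from sfps import (build_model_topology, BDProtocol, simulate_trajectory,
                  site_occupancy, cluster_binding_modes, ion_spec)
from sfps.binding import analysis_window
from sfps.interactions import classify_mode_coordination

top = build_model_topology("DEKA", seed=11)
traj = simulate_trajectory(top, BDProtocol(n_steps=40_000,
                                           save_interval=20, seed=12))
ion = top.indices(role="ion")[0]
fractions, labels = site_occupancy(traj, top, ion)
print({k: round(v, 2) for k, v in fractions.items() if v > 0})

window = analysis_window(traj.n_frames)          # final 75% of frames
bound = [f for f in window if labels[f] == "Site_OC"]
modes = cluster_binding_modes(traj, top, ion, bound,
                              n_analyzed_frames=len(window))
coord = classify_mode_coordination(modes[0], traj, top, ion, ion_spec("NA"))
print(round(modes[0].occupancy, 2), round(coord["mean_carboxylate_O"], 2),
      coord["tight_coordination"])
```

Output:

```
{'Site_HFS': 0.65, 'Site_OC': 0.23, 'unbound': 0.12}
0.12 3.12 True
```

The Na⁺ ion spends about a quarter of the run at the outer constriction
site; its largest binding mode there is coordinated by just over three
carboxylate oxygens of the inner-ring Asp/Glu — the tight, Na⁺-favouring
geometry enforced by the centrally protruding Lys charge.  Feeding that
mode to the FEP engine (`sfps.fep.run_fep_leg` for the bound and bulk
legs, `sfps.fep.ddG`) yields a positive ΔΔG(Na⁺→K⁺); repeating the
workflow for DERA yields a strictly smaller value, reproducing the
mechanism qualitatively.

A configured end-to-end run (trajectory, tables, manifest) is available
from the command line:

```bash
sfps default-config -o run.cfg
sfps analyze -c run.cfg      # all tables, FEP off
sfps fep -c run.cfg          # adds the ddG summary
sfps report -d sfps_out
```

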