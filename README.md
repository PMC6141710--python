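# intercells

Agent-based lattice Monte-Carlo simulation of molecular patterning at
intercellular interfaces — in particular the early immune synapse between a
T cell and a stimulating coverslip or an antigen-presenting cell (APC) —
together with the SMLM-style spatial statistics (topology / Minkowski-
perimeter conditional densities and pair-correlation functions) used to
compare simulated and experimentally imaged point patterns.

The package is for quantitative cell biologists and biophysicists who want
to test kinetic-segregation-type hypotheses: given receptor sizes,
stiffnesses, binding wells and membrane mechanics, which nanoscale
arrangements of TCR, integrins (CD11/LFA-1) and bulky glycoproteins (CD45)
emerge in the first ~100 s of contact, and how do they compare with
single-molecule localization microscopy (PALM/dSTORM) data?

## Model

The interface is a periodic square lattice of pixels of size *a* = 10 nm.
Each pixel *i* carries the local membrane–surface separation *z<sub>i</sub>*
(nm) and at most one molecule per surface.  The Hamiltonian (energies in
kT) is *H* = *H*<sub>int</sub> + *H*<sub>el</sub> with

- binding wells: *V*<sub>mol–lig</sub>(*z*) = *U* for |*z* − *l*<sub>complex</sub>| < *w*, else 0
  (TCR–αCD3/pMHC at 13 nm, CD11–ICAM at 35 nm, plus an optional
  non-specific PLL well);
- compressional springs: *V*<sub>mol</sub>(*z*) = *k*(*z* − *l*<sub>mol</sub>)² for *z* < *l*<sub>mol</sub>, else 0
  (CD45, with *l* = 40 nm, is the dominant repulsive element);
- optional nearest-neighbour self-clustering energies *J* for TCR and CD11;
- bending: *H*<sub>el</sub> = Σ<sub>i</sub> κ/(2*a*²) (Δ<sub>d</sub>*z<sub>i</sub>*)², the discrete
  Laplacian squared with effective rigidity κ = κ₁κ₂/(κ₁+κ₂).

Dynamics per 0.01 s iteration: every mobile molecule attempts a hop to one
of its 4 neighbours with probability 4*D*d*t*/*a*² (occupied targets are
rejected); hops are accepted with the two-stage Metropolis product
*P*(old→free)·*P*(free→new); colliding accepted hops are resolved in favour
of the largest energy gain; then every unpinned pixel receives one Gaussian
height proposal Δ*z* ~ N(0, 1 nm²) accepted by the Metropolis criterion.
Pixels holding TCR or CD11 pin the separation at 13 nm / 35 nm.  An
optional centripetal translocation biases chosen species toward a target at
constant speed (19 nm/s by default).  Runs are bit-reproducible from a seed.

## Worked example

```python
import numpy as np
import intercells as ic

bundle = ic.build_scenario({
    "grid": {"n_rows": 256, "n_cols": 256},       # 2.56 x 2.56 um^2
    "run": {"n_steps": 5000, "seed": 11, "save_every": 2500},
})
sim = bundle.build()
trajectory = sim.run()
print("simulated time:", trajectory.total_time, "s")
print("membrane acceptance:", round(trajectory.height_acceptance(start=2500), 3))

snap = trajectory.snapshots[-1]
points = {s: snap.molecules.query("species == @s")[["x_nm", "y_nm"]].to_numpy()
          for s in ("TCR", "CD45", "CD11")}
radii = np.arange(20.0, 420.0, 20.0)
curves = ic.topology_analysis(points["TCR"],
                              {"CD45": points["CD45"], "CD11": points["CD11"]},
                              radii, pixel_size=10.0, window=(2560.0, 2560.0))
for name, pk in ic.peak_shift(curves).items():
    print(f"{name}: peak at {pk.peak_radius:.0f} nm")
print("TCR g(r<20nm):", round(float(curves.ref_pcf[0]), 1))
```

prints

```
simulated time: 50.0 s
membrane acceptance: 0.436
CD45: peak at 120 nm
CD11: peak at 60 nm
TCR g(r<20nm): 17.9
```

Reading: after 50 s of simulated contact on an αCD3-coated coverslip the
membrane height moves are accepted at 43.6% (inside the 40–50% tuning
window); TCR remains strongly self-clustered (pair correlation ≈ 18 in the
first 20 nm band); the conditional density of CD11 around TCR clusters
peaks at 60 nm while CD45 peaks at 120 nm — the mutual TCR → CD11 → CD45
ordering of the early synapse.

A command-line interface wraps the same library:

```bash
intercells run --config scenario.yaml --seed 1 --out out/
intercells batch --scan initial.CD45.density_per_um2=0.5x,1x,2x --out scan/
intercells analyze --ref tcr.csv --other CD45 cd45.csv --window 2560 2560 --out curves.csv
intercells synth --kind gaussian_clusters \
    --params '{"n_clusters": 8, "pts_per_cluster": 60, "cluster_sd": 50, "window": [2560, 2560]}' \
    --out tcr.csv
```

Initial conditions can also come from ThunderSTORM-style localization CSVs
(`x [nm]`/`y [nm]` columns) via `read_localizations` / recipe kind
`localizations`.

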