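# k2pflex

Trajectory analysis for mechanosensitive two-pore-domain (K2P) potassium
channel gating.

Mechanosensitive K2P channels (TREK-1, TREK-2, TRAAK) switch between two
principal conformations — "down" and "up" — in direct response to
membrane tension, following the force-from-lipid principle: the channel
is gated by changes in the forces within the bilayer rather than by
tethers. Analysing that behaviour in MD trajectories requires a specific
toolbox, which this package provides as a tested, reusable pipeline:

* **Conformational state** — Cα RMSD of the TM helices (M1–M4) against
  the down/up reference structures (Kabsch superposition); the three
  per-chain gating distances — *fenestration* (G324 Cα ↔ P198 Cα of the
  adjacent chain), *zipper* (W326 ↔ R237) and *expansion* (M322 ↔ G212);
  down/up/intermediate state labels; a conformational-landscape table
  with crystal-structure reference rows; and change-point detection of
  the event sequence **unzip → expand → close**, per chain.
* **Membrane geometry** — cross-sectional area profile A(z) of the
  protein's van-der-Waals envelope (rasterised union of disks per
  z-slice, in nm²), bilayer thickness as the distance between head-group
  phosphate planes, and area per lipid `Lx·Ly / n_lipids_per_leaflet`.
* **Lateral pressure profile** — a z-binned local stress tensor by the
  Hardy / Irving–Kirkwood–Noll construction,
  `σ(b) = −(1/V_b)[Σ_i m_i v_i⊗v_i + Σ_(i,j) w_b(i,j) r_ij⊗f_ij]`,
  with each pair's contribution distributed along the minimum-image
  segment (top-hat bond function, exact partition of unity), then
  `P = −σ`, `P_∥ = (P_xx+P_yy)/2`, `P_⊥ = P_zz`,
  `P_L(z) = P_∥(z) − P_⊥(z)` and the surface tension `γ = −∫P_L dz`.
* **Occupancy** — selectivity-filter ion occupancy over the S0–S4
  sites, pore water density in a cylinder with dewetting-interval
  detection, and lipid-tail contact series at the fenestration (bound =
  within 4 Å of P198) and the M2/M3-tip groove (F226–L243 width vs
  lipid distance from S240).
* **Synthetic data** — generators for every input class with recorded
  ground truth: idealised two-chain down/up channel models and noisy
  planted transitions, planar bilayers, pore ion/water traces, and
  particle systems with analytically known forces (ideal gas, harmonic
  pair, truncated Lennard-Jones) for validating the stress machinery.

Residue numbers are PDB author numbers throughout (G324 means author
resid 324). Boxes are orthorhombic; triclinic input is rejected.

## Worked example

Generate a noisy synthetic transition with planted per-chain events and
recover them:

```sh
k2pflex synth transition --out demo --seed 3 --n-frames 100 --noise-sd 0.6
k2pflex events --trajectory demo/transition.xyzb --out demo
cat demo/events.json
```

```json
{
  "events_ps": {
    "A": {
      "unzip": 20.0,
      "expand": 40.0,
      "close": 60.0
    },
    "B": {
      "unzip": 30.0,
      "expand": 50.0,
      "close": 70.0
    }
  },
  "order_ok": {
    "A": true,
    "B": true
  }
}
```

The generator planted the unzip/expand/close events at 20/40/60 ps on
chain A and 30/50/70 ps on chain B (written to
`demo/transition.truth.json`); the detector recovers each one from the
midpoint crossing of the smoothed distance series, and `order_ok`
confirms that unzipping precedes expansion and fenestration closure on
both chains — the sequence observed in stretch simulations.

The same workflow applies to real inputs: pass a PDB topology and an
XTC/DCD trajectory to `rmsd`, `gating`, `classify`, `events`,
`area-profile`, `bilayer`, `pressure`, `ions`, `water` or `lipids`, or
run everything at once with `k2pflex report --config run.toml`, which
also writes a provenance manifest (package version, config hash, file
checksums). All thresholds live in a single TOML config
(`src/k2pflex/data/defaults.toml` documents the defaults).

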