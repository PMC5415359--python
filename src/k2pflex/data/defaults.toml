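# Shipped analysis defaults.  Every threshold used by an analysis is
# defined here (or overridden by a user config), never hard-coded in
# analysis code, so the parameters behind any output are auditable.

[gating]
fenestration = [324, 198]   # own-chain M4 resid, adjacent-chain M2 resid
zipper = [326, 237]
expansion = [322, 212]
atom_mode = "CA"            # or "min-heavy"

[gating.adjacency]
A = "B"
B = "A"

[reference_distances.down]
fenestration = 12.0
zipper = 6.0
expansion = 8.0

[reference_distances.up]
fenestration = 6.0
zipper = 14.0
expansion = 14.0

[state]
margin = 0.5                # Å, RMSD gap below which a frame is "intermediate"
smoothing_window = 5        # frames, moving average before event detection
dwell = 5                   # frames a crossing must persist to count
stride = 1                  # frames between landscape samples

[area]
slice_thickness = 1.0       # Å
raster = 0.25               # Å
z_origin = "centroid"       # "midplane" | "centroid" | fixed number

[pressure]
bin_width = 1.0             # Å (0.1 nm)
kinetic_mode = "velocities" # or "thermal" (requires temperature)

[selections.phosphates]
atom_names = ["P"]

[selections.ions]
atom_names = ["K"]

[selections.waters]
atom_names = ["OW"]

[selections.lipid_tails]
resnames = ["LIP", "POPC", "DLPC"]
exclude_names = ["P", "O11", "O12", "O13", "O14", "N", "C11", "C12", "C13", "C14", "C15"]

[occupancy]
dewetting_threshold = 5.0   # waters; counts below this are "dry"
dewetting_min_duration = 1  # frames
cylinder_radius = 5.0       # Å
cavity_z = [-12.0, 0.0]     # Å, z-interval of the inner cavity
contact_threshold = 4.0     # Å, lipid "bound" criterion
fenestration_target = 198   # residue whose lipid contacts are tracked
groove_pair = [226, 243]
groove_anchor = 240

[[occupancy.sites]]
name = "S0"
z = [12.0, 15.0]

[[occupancy.sites]]
name = "S1"
z = [9.0, 12.0]

[[occupancy.sites]]
name = "S2"
z = [6.0, 9.0]

[[occupancy.sites]]
name = "S3"
z = [3.0, 6.0]

[[occupancy.sites]]
name = "S4"
z = [0.0, 3.0]
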