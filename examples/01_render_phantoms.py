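"""Render synthetic phase-image phantoms with exact analytic ground truth.

Every downstream capability in this package is validated against these
phantoms: each rendered object carries its true area, dry mass, sphericity
and length/width ratio, computed from the generating solid, not from pixels.
"""

from pathlib import Path

from qpihuvec import (CellPhantomSpec, DebrisSpec, OpticsConfig, render_cell,
                      render_field)
from qpihuvec import io as qio

out = Path("scratch/examples/phantoms")
out.mkdir(parents=True, exist_ok=True)
optics = OpticsConfig()  # 0.5 µm/px, Δn = 0.04, α = 0.18 µm³/pg

# --- a single cell with a calibrated dry mass -------------------------------
spec = CellPhantomSpec("spherical_cap", footprint_radii=(15.0, 15.0),
                       height=6.0, dry_mass=80.0)
image, truth = render_cell(spec, optics=optics, canvas=(128, 128))
obj = truth.objects[0]
print(f"single cell: area {obj.area:.1f} µm², dry mass {obj.dry_mass:.1f} pg, "
      f"sphericity {obj.sphericity:.3f}")
qio.write_phase_tiff(image, out / "single_cell.tif")

# --- a field of cells plus sub-gate debris ----------------------------------
cells = [CellPhantomSpec("ellipsoidal_cap", (1.66 * b, b), 0.3 * b)
         for b in (10.0, 11.0, 12.0, 13.0, 14.0, 15.0)]
field, field_truth = render_field(cells, DebrisSpec(count=2), optics=optics,
                                  canvas=(600, 600), seed=7)
print(f"field: {len(field_truth.objects)} objects, "
      f"{field_truth.debris_percent:.1f}% debris by truth, "
      f"total dry mass {field_truth.total_dry_mass:.0f} pg")
qio.write_phase_tiff(field, out / "field.tif")
print(f"wrote phase TIFFs (with JSON sidecars) to {out}")
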