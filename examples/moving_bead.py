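"""Fast-moving bead: motion elongation at a fixed volumetric rate.

A 10-um bead translates along x at 6000 um/s over 200 um while being
imaged at ~30.6 vps.  Each volume takes ~33 ms to acquire, during which
the bead moves up to ~200 um x the duty fraction of that window, so its
reconstruction is smeared along x.  The script prints the tracked x
centroid and the apparent x extent of the bead per volume.  A reduced
pulse rate keeps this demo quick; the geometry of the smear is unchanged.
"""

import numpy as np

from lissavol import ClockConfig, Geometry, ScanConfig, iter_volumes, translating_bead
from lissavol.metrics import volume_centroid

cfg = ScanConfig(
    clocks=ClockConfig(f_rep=8e6),
    geometry=Geometry(fov_x=343.0, fov_y=80.0, fov_z=120.0),
)
ph = translating_bead(speed=6000.0, travel=200.0, start=(-100.0, 0.0, 0.0))

print(f"volume rate: {cfg.volume_rate:.1f} vps  (n_y = {cfg.geometry.n_y} lines)")
print("volume  t_mid_s  x_centroid_um  x_extent_um")
for i, vol in enumerate(iter_volumes(ph, cfg, 5, seed=0, noise=False)):
    c = volume_centroid(vol)
    signal = np.where(vol.hits > 0, np.nan_to_num(vol.values), 0.0)
    profile = signal.sum(axis=(1, 2))
    lit = np.nonzero(profile > 0.05 * profile.max())[0]
    xs = (lit + 0.5) / cfg.geometry.n_x * cfg.geometry.fov_x - cfg.geometry.fov_x / 2
    print(f"  {i}     {vol.t_mid:.3f}      {c[0]:+7.1f}       {xs.max() - xs.min():6.1f}")
print(
    "\nWhile the bead is in flight (volume 0) its apparent x extent far "
    "exceeds the 10-um diameter — it moves ~25 um during the ~4 ms in "
    "which the scan crosses its y lines (motion elongation).  Once the "
    "stage stops at +100 um the extent relaxes back to the bead size."
)
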