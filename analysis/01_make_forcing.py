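"""Build the synthetic zonal SST climatology driving all experiments.

Writes results/climatology.csv (1° latitude rows x 365 day columns) and
prints its gross structure: annual means fall from ~28 °C at the equator
toward freezing poleward, and the seasonal range peaks near 40° latitude
while vanishing at the equator and poles — the features of an observed
zonally averaged climatology the model needs.
"""

import importlib
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
common = importlib.import_module("00_common")

import thermoniche as tn

args = common.study_args(__doc__)
lats = np.arange(np.ceil(args.latitude_band[0]), np.floor(args.latitude_band[1]) + 0.5)
clim = tn.synthesize_climatology(tn.SyntheticForcingParams(seed=args.seed), lats)
clim.to_csv(common.RESULTS / "climatology.csv")

means = clim.annual_mean()
amp = np.array([tn.temperature_amplitude(clim, b) for b in range(clim.n_boxes)])
print(f"climatology: {clim.n_boxes} boxes, lat {lats[0]:g}..{lats[-1]:g} °N")
print(f"annual means {means.min():.1f}..{means.max():.1f} °C "
      f"(equatorward maximum at {clim.latitudes[np.argmax(means)]:g}°)")
print(f"seasonal range 0..{amp.max():.1f} °C, peaking at "
      f"{clim.latitudes[np.argmax(amp)]:g}°")
print(f"wrote {common.RESULTS / 'climatology.csv'}")
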