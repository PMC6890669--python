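"""Run the full analysis pipeline on a simulated movie and compare with truth.

PIV -> outlier validation/fill -> regularized traction inversion ->
per-frame strain energy, mean traction and RMS displacement, exactly as
one would analyze a real bead-channel recording (the final frame is the
stress-free reference, mimicking detaching the cells at the end).
Takes ~1 min on one CPU (512 px field of view, 3 frames).
"""

import numpy as np

from tfmkit import ElasticSubstrate, default_scene_movie
from tfmkit.metrics import movie_metrics

movie = default_scene_movie(n_frames=3, young_modulus=3000.0, seed=7)
table = movie_metrics(movie.sequence, ElasticSubstrate(3000.0, 0.45))

est = table["strain_energy_per_area_pN_per_um"].to_numpy()
gt = movie.ground_truth["strain_energy_per_area_pN_per_um"].to_numpy()

print(table[["frame", "timestamp_min", "strain_energy_per_area_pN_per_um",
             "mean_traction_Pa", "rms_displacement_um"]].round(3).to_string(index=False))
print()
for i, (e, g) in enumerate(zip(est, gt)):
    print(f"frame {i}: recovered energy density {e:7.3f} pN/um, "
          f"ground truth {g:7.3f}, ratio {e / g:.3f}")
print()
print("Ratios near 1 mean the pipeline recovers the work the monolayer")
print("imparts to the gel from bead images alone; in the display units of")
print("monolayer mechanics, 1 pN/um = 1e-3 nN/um.")
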