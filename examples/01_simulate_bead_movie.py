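"""Simulate a synthetic TFM recording with known ground truth.

Builds the default benchmark scene — a confluent-monolayer-like traction
field on a 3 kPa gel, imaged as fluorescent bead frames at 10-min
cadence — and prints the per-frame ground-truth mechanics.
"""

from tfmkit import default_scene_movie

movie = default_scene_movie(n_frames=4, young_modulus=3000.0, seed=42)

print(f"frames (incl. final stress-free reference): {len(movie.sequence)}")
print(f"image size: {movie.sequence[0].shape}, pixel size "
      f"{movie.sequence.pixel_size} um/px")
print()
print(movie.ground_truth.round(3).to_string(index=False))
print()
print("strain_energy_per_area is the work the simulated monolayer stores in")
print("the gel per um^2 of field of view (pN/um; divide by 1000 for nN/um);")
print("rms_displacement is the bead-scale deformation the pipeline must recover.")
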