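"""Render sweeping-bar aperture movies for retinotopic mapping.

Builds the binary stimulus masks a pRF analysis consumes: bars of 1, 2 and
3 degrees sweeping in eight directions over a +/-10 degree field, one
frame per 2 s TR, with blank frames between sweeps.
"""

from topomem import stimulus

grid = stimulus.make_grid(extent_deg=10.0, n_pix=64)
print(f"grid: {grid.n_pix} x {grid.n_pix} pixels, "
      f"{grid.pixel_spacing:.3f} deg spacing")

parts = [stimulus.default_mapping_movie(grid, width_deg=w, tr_s=2.0)
         for w in (1.0, 2.0, 3.0)]
movie = stimulus.concat_movies(parts)

# frames are binary masks; mean activity is the fraction of field stimulated
print(f"movie: {movie.n_frames} frames "
      f"({movie.n_frames * movie.tr_s / 60:.1f} min of scanning), "
      f"mean frame activity {movie.frames.mean():.3f}")

stimulus.save_movie(movie, "apertures.npz")
print("wrote apertures.npz (binary masks + grid metadata)")
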