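"""Preprocess one spectrum into the 1,600-feature network input.

Synthesizes a caffeine/fentanyl mixture, then runs the fixed chain:
validation (>= 1,626 points covering 600-3,800 cm^-1), natural cubic-spline
resampling onto the even-wavenumber grid 600, 602, ..., 3,798 cm^-1, and
standardization to zero mean / unit population SD.
"""

import numpy as np

from ftirnet import (
    MixtureSpec,
    SimConfig,
    default_library,
    preprocess_spectrum,
    synthesize_spectrum,
    validate_spectrum,
)

lib = default_library()
mix = MixtureSpec(weights={"fentanyl": 0.08, "caffeine": 0.92}, noise_sd=0.001)
spectrum = synthesize_spectrum(lib, mix, SimConfig().grid,
                               np.random.default_rng(0), sample_id="demo")

verdict = validate_spectrum(spectrum)
print(f"validation: {'accept' if verdict else verdict.reason} "
      f"({spectrum.n_points} points, "
      f"{spectrum.wavenumbers[0]:.0f}-{spectrum.wavenumbers[-1]:.0f} cm^-1)")

fv = preprocess_spectrum(spectrum)
print(f"feature vector: {len(fv.values)} values, "
      f"mean {fv.values.mean():.2e}, sd {fv.values.std():.6f}")
# the standardized vector is what the convolutional network consumes
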