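"""Noise robustness of the half-visible filtered current image.

Additive white Gaussian noise on the retina samples is largely rejected by
the spectral filter (197 of 4096 pixels survive), so the filtered current
magnitude image barely changes even at SNR 10 dB.
"""

import numpy as np

from mwcam import (
    CameraGeometry,
    GridSpec,
    TissueDielectrics,
    add_awgn,
    backproject,
    born_forward,
    build_phantom,
    diffraction_map,
    field_spectrum,
    jitter_dielectrics,
    ssim,
    visible_filter,
)
from mwcam.phantoms import enumerate_heldout_configs
from mwcam.spectral import SpectralGrid

geometry = CameraGeometry()
sgrid = SpectralGrid(geometry)
config = enumerate_heldout_configs(n_rotations=1, include_mirrors=False)[0]
dielectrics = jitter_dielectrics(TissueDielectrics(), config.jitter_seed)
phantom = build_phantom(config, dielectrics, GridSpec(), geometry)
retina = born_forward(phantom, geometry)


def filtered_current(field):
    j_hat = diffraction_map(field_spectrum(field, geometry), sgrid)
    return backproject(visible_filter(j_hat, fraction=0.5))


clean = np.abs(filtered_current(retina.field))
for snr_db in (20.0, 10.0):
    noisy = np.abs(filtered_current(add_awgn(retina, snr_db, seed=0).field))
    print(f"SNR {snr_db:>4.0f} dB: SSIM(noisy |j_z|, clean |j_z|) = {ssim(noisy, clean):.3f}")
# Values near 1 mean the filtered image is nearly unchanged: the evanescent
# and out-of-band spectral components that carry most of the noise are
# discarded before imaging.
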