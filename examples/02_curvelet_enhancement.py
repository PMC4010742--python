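"""Denoise a broken microglia process by curvelet hard thresholding.

A tube with a 2-voxel break is corrupted with noise, enhanced slice-wise in
the curvelet domain, and checked for gap closure and SNR gain.
"""

import numpy as np
from scipy import ndimage

from microtrace import enhance
from microtrace.imgio import Volume

rng = np.random.default_rng(11)
img = np.zeros((3, 64, 128))
img[1, 31:34, 6:63] = 1200.0
img[1, 31:34, 65:122] = 1200.0          # 2-voxel gap
noisy = np.clip(img + rng.normal(0, 150, img.shape), 0, 16383)
v = Volume(noisy.astype(np.uint16), depth=14, channel="microglia")

out, orient = enhance.enhance_arbors(v, kappa=6.0, n_scales=5, tile=128)

sl = out.data[1].astype(float)
labels, _ = ndimage.label(sl > sl.max() / 2, structure=np.ones((3, 3)))
snr = lambda x: 10 * np.log10(np.sum(img[1] ** 2) / np.sum((x - img[1]) ** 2))
print(f"SNR before: {snr(noisy[1]):.1f} dB,  after: {snr(sl):.1f} dB")
print(f"tube fragments connected across the gap: "
      f"{labels[32, 20] == labels[32, 108] != 0}")
ang = np.degrees(orient.angle[1, 32, 10:50])
err = np.minimum(ang, 180 - ang)          # distance from horizontal, mod 180
print(f"median orientation error along the tube: {np.median(err):.1f} deg "
      f"(wedge quantization ~11 deg)")
# The SNR gain and the reconnected fragments are what the downstream tracer
# relies on; the orientation map localizes the tube's direction per pixel.
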