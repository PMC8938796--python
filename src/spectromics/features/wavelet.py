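"""One-level 3D wavelet sub-band images on the original grid.

The volume is decomposed with a single-level separable 3D discrete wavelet
transform (orthogonal Coiflet-1 by default, periodization boundary handling
on an even-padded grid).  Each of the 8 low/high-pass axis combinations is
reconstructed back to the original grid with every other coefficient set
zeroed, yielding band-limited images labelled LLL..HHH.  Because the
transform is orthogonal, the reconstructed sub-bands are mutually orthogonal
projections and their energies sum to the input energy (Parseval), and they
sum voxelwise to the original volume.
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["wavelet_subbands", "SUBBAND_NAMES"]

#: L/H labels per axis, in the fixed order produced here.
SUBBAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _key_to_name(key: str) -> str:
    return "".join("L" if c == "a" else "H" for c in key)


def wavelet_subbands(volume: np.ndarray, wavelet: str = "coif1") -> dict:
    """Decompose a 3D volume into its 8 one-level wavelet sub-band images.

    Returns ``{name: volume}`` with names LLL..HHH; every sub-band has the
    shape of the input.  Raises if any dimension is shorter than the
    wavelet's filter length.
    """
    volume = np.asarray(volume, float)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    w = pywt.Wavelet(wavelet)
    if min(volume.shape) < w.dec_len:
        raise ValueError(
            f"volume dimensions {volume.shape} shorter than the {wavelet} "
            f"filter length {w.dec_len}"
        )
    # pad to even sizes so the periodized DWT is exactly orthogonal
    pad = [(0, n % 2) for n in volume.shape]
    padded = np.pad(volume, pad, mode="edge")

    coeffs = pywt.dwtn(padded, w, mode="periodization")
    out = {}
    for key, arr in coeffs.items():
        single = {k: (arr if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
        rec = pywt.idwtn(single, w, mode="periodization")
        rec = rec[tuple(slice(0, n) for n in volume.shape)]
        out[_key_to_name(key)] = rec
    return {name: out[name] for name in SUBBAND_NAMES}
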