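"""Plain-text exports: NMD mode/arrow files, spring pair lists, CSV tables."""

from __future__ import annotations

import numpy as np

from .enm import Spectrum
from .structures import CalphaModel


def write_nmd(
    path,
    model: CalphaModel,
    mode_vectors: np.ndarray,
    mode_labels=None,
    title: str = "icenm modes",
) -> None:
    """Write modes or arrow fields in NMD format for visualization.

    ``mode_vectors`` is (3N, K) or (N, 3) for a single arrow field.  NMD is
    the plain-text exchange format used by normal-mode viewers: one
    ``coordinates`` line plus one ``mode`` line per vector.
    """
    vecs = np.asarray(mode_vectors, dtype=float)
    if vecs.ndim == 2 and vecs.shape == (len(model), 3):
        vecs = vecs.reshape(-1)[:, None]
    elif vecs.ndim == 1:
        vecs = vecs[:, None]
    if vecs.shape[0] != 3 * len(model):
        raise ValueError("mode vectors do not match the model size")
    if mode_labels is None:
        mode_labels = [str(k + 1) for k in range(vecs.shape[1])]
    with open(path, "w") as fh:
        fh.write(f"title {title}\n")
        fh.write("names " + " ".join("CA" for _ in range(len(model))) + "\n")
        fh.write("resids " + " ".join(str(r) for r in model.res_numbers) + "\n")
        fh.write("chainids " + " ".join(str(c) for c in model.chain_ids) + "\n")
        fh.write(
            "coordinates "
            + " ".join(f"{v:.3f}" for v in model.coords.reshape(-1))
            + "\n"
        )
        for k in range(vecs.shape[1]):
            fh.write(
                f"mode {mode_labels[k]} "
                + " ".join(f"{v:.6f}" for v in vecs[:, k])
                + "\n"
            )


def write_spectrum_csv(path, spectrum: Spectrum) -> None:
    """Mode index (1-based over nonzero modes) and eigenvalue table."""
    import pandas as pd

    w, _ = spectrum.nonzero_modes()
    pd.DataFrame(
        {"mode_index": np.arange(1, len(w) + 1), "eigenvalue": w}
    ).to_csv(path, index=False)


def write_pair_list(path, frame) -> None:
    """PyMOL-loadable plain-text selector pairs, one spring per line."""
    with open(path, "w") as fh:
        for _, row in frame.iterrows():
            fh.write(
                f"chain {row.chain_i} and resi {row.res_i} and name CA\t"
                f"chain {row.chain_j} and resi {row.res_j} and name CA\n"
            )
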