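"""Result serialization (HDF5 / CSV) and storage-size bookkeeping.

HDF5 layout (public interface): datasets ``t`` (T,), ``phi``
(n_contacts × T), and optionally ``v`` and ``imem`` (N × T).  CSV output is
a fallback for small results: one header line, then rows ``t, phi_0, …``.

A streaming HDF5 writer is provided so contact potentials can be written
one time step at a time during a runtime-sink simulation; the resulting file
is identical to one written post hoc.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "write_result",
    "read_result",
    "StreamingH5Writer",
    "estimate_storage_bytes",
    "estimate_storage_mb",
]


def write_result(path, t, phi, v=None, imem=None, format: str = "h5") -> None:
    """Write a result to ``path`` in the given format ('h5' or 'csv').

    The HDF5 format is lossless (float64 round trip); CSV stores t and phi
    only, at full repr precision.
    """
    t = np.asarray(t, dtype=float)
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if format == "h5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=t)
            f.create_dataset("phi", data=phi)
            if v is not None:
                f.create_dataset("v", data=np.asarray(v, dtype=float))
            if imem is not None:
                f.create_dataset("imem", data=np.asarray(imem, dtype=float))
    elif format == "csv":
        header = "t," + ",".join(f"phi_{k}" for k in range(phi.shape[0]))
        data = np.column_stack([t, phi.T])
        np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_result(path, format: str = "h5") -> dict:
    """Read a result written by :func:`write_result`; returns a dict with
    't', 'phi' and, when present, 'v' and 'imem' arrays."""
    if format == "h5":
        import h5py

        out = {}
        with h5py.File(path, "r") as f:
            for k in ("t", "phi", "v", "imem"):
                if k in f:
                    out[k] = f[k][...]
        return out
    if format == "csv":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        data = np.atleast_2d(data)
        return {"t": data[:, 0], "phi": data[:, 1:].T}
    raise ValueError(f"unknown format {format!r}")


class StreamingH5Writer:
    """Write contact potentials to HDF5 one time step at a time.

    Produces a file identical to post-hoc :func:`write_result` output for the
    same data (same datasets, dtype and values).
    """

    def __init__(self, path, n_contacts: int, n_steps: int):
        import h5py

        self._f = h5py.File(path, "w")
        self._t = self._f.create_dataset("t", shape=(n_steps,), dtype="f8")
        self._phi = self._f.create_dataset(
            "phi", shape=(n_contacts, n_steps), dtype="f8"
        )
        self._k = 0

    def append(self, t: float, phi: np.ndarray) -> None:
        self._t[self._k] = t
        self._phi[:, self._k] = phi
        self._k += 1

    def close(self) -> None:
        self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def estimate_storage_bytes(
    n_compartments: int, duration_s: float, rate_hz: float, bytes_per_sample: int = 8
) -> int:
    """Raw uncompressed size of a full membrane-current recording.

    n_compartments × (duration × sampling rate) samples at
    ``bytes_per_sample`` each; e.g. 1000 compartments for 1 s at 20 kHz in
    64-bit floats is 160 MB.
    """
    if n_compartments < 1 or duration_s <= 0 or rate_hz <= 0 or bytes_per_sample < 1:
        raise ValueError("all storage-estimate arguments must be positive")
    return int(round(n_compartments * duration_s * rate_hz * bytes_per_sample))


def estimate_storage_mb(
    n_compartments: int, duration_s: float, rate_hz: float, bytes_per_sample: int = 8
) -> float:
    """Storage estimate in MB (1 MB = 10⁶ bytes)."""
    return estimate_storage_bytes(
        n_compartments, duration_s, rate_hz, bytes_per_sample
    ) / 1e6
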