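"""Shared fixtures: synthetic FCS files and small simulated screens."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from gridscreen.core import EventTable
from gridscreen.simulate import PopulationSpec, simulate_screen


def write_minimal_fcs(path, data: np.ndarray, channels: list[str],
                      datatype: str = "F") -> None:
    """Write a synthetic FCS 3.0 list-mode file (test fixture generator).

    Single dataset, float32 ("F") or float64 ("D") little-endian.  Only the
    keywords needed by a list-mode reader are emitted.
    """
    data = np.asarray(data, dtype=np.float64)
    n_tot, n_par = data.shape if data.size else (0, len(channels))
    nbytes, np_dtype = (4, "<f4") if datatype == "F" else (8, "<f8")

    text_start = 58
    text_reserved = 2048
    data_start = text_start + text_reserved
    data_len = n_tot * n_par * nbytes
    data_end = data_start + data_len - 1 if data_len else 0

    kv = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BEGINDATA": str(data_start), "$ENDDATA": str(max(data_end, 0)),
        "$BYTEORD": "1,2,3,4", "$DATATYPE": datatype, "$MODE": "L",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_tot),
    }
    for i, name in enumerate(channels, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = str(nbytes * 8)
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = "262144"
    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
    text_bytes = text.encode("ascii")
    assert len(text_bytes) <= text_reserved
    text_end = text_start + len(text_bytes) - 1

    header = b"FCS3.0    "
    header += f"{text_start:>8d}{text_end:>8d}".encode()
    header += f"{data_start:>8d}{max(data_end, 0):>8d}".encode()
    header += f"{0:>8d}{0:>8d}".encode()

    body = b""
    if data_len:
        body = data.astype(np_dtype).tobytes()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(b" " * (text_reserved - len(text_bytes)))
        fh.write(body)


@pytest.fixture
def fcs_writer():
    return write_minimal_fcs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table(rng) -> EventTable:
    return EventTable(rng.normal(size=(200, 3)), ("CD11b", "Gr-1", "CD16_32"))


def two_population_specs(d: int = 3) -> list[PopulationSpec]:
    lo = tuple([0.0] * d)
    hi = tuple([6.0] * d)
    return [PopulationSpec(lo, tuple([1.0] * d), 0.6),
            PopulationSpec(hi, tuple([1.0] * d), 0.4)]


@pytest.fixture
def tiny_screen():
    """6 controls + one drug at 2 doses, 2 replicates; no artifacts."""
    from gridscreen.simulate import DrugEffectSpec
    pops = two_population_specs()
    drugs = [DrugEffectSpec("drugA", 0, "mean_shift", (4.0, 0.0, 0.0),
                            hill_midpoint=0.1, hill_slope=1.0)]
    return simulate_screen(pops, drugs, doses=[0.01, 10.0],
                           wells_per_condition=2, events_per_well=400,
                           seed=42, n_controls=6)
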