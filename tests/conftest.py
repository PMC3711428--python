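"""Shared fixtures for the test suite."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from utrtune.synthetic_flow import ConstructSpec, SimulationConfig


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    """Identity spillover, no autofluorescence, no dead cells."""
    return SimulationConfig(n_events=5_000, seed=11).noiseless()


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(n_events=20_000, seed=11)


def make_construct(e: float = 0.5, motif: str = "Kt", reporter: str = "EGFP",
                   distance: int = 18, copies: int = 1,
                   name: str | None = None) -> ConstructSpec:
    return ConstructSpec(name=name or f"{motif}-{reporter}-test", motif=motif,
                         distance_nt=distance, copies=copies,
                         reporter=reporter, true_efficiency=e)


def write_minimal_fcs(path, data: np.ndarray, channel_names: list[str]
                      ) -> None:
    """Write a minimal FCS 3.0 list-mode file (float32, little-endian).

    Serves as the reference writer for the read-only FCS ingestion tests;
    the binary file lives only in the test's temporary directory.
    """
    n_events, n_par = data.shape
    assert len(channel_names) == n_par
    payload = data.astype("<f4").tobytes()

    delim = "/"
    keywords = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_events),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = "262144"

    # iterate: text length depends on the data offsets it encodes
    header_len = 58
    text_start = header_len
    data_start = 0
    for _ in range(3):
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in
                                  sorted(keywords.items())) + delim
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(payload) - 1
        header = (f"FCS3.0    {text_start:>8d}{text_end:>8d}"
                  f"{data_start:>8d}{data_end:>8d}{0:>8d}{0:>8d}")
        assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text.encode("ascii"))
        fh.write(payload)
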