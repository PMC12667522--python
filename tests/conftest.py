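import numpy as np
import pandas as pd
import pytest

from phosphodyn import PhosphoSites, QuantMatrix, SampleDesign


@pytest.fixture
def design4():
    """Four ordered stages x four replicates (the stage-series layout)."""
    return SampleDesign.from_layout(
        ["step1-2", "step3-4", "step5-6", "step13-14"], 4)


@pytest.fixture
def design2x2():
    """Two stages x two replicates: the smallest valid design."""
    return SampleDesign.from_layout(["g1", "g2"], 2)


@pytest.fixture
def make_quant():
    def _make(rows: dict, design) -> QuantMatrix:
        frame = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=list(design.samples),
                                       dtype=float)
        return QuantMatrix(frame, design)
    return _make


@pytest.fixture
def make_sites():
    def _make(rows: list[dict], design) -> PhosphoSites:
        frame = pd.DataFrame(rows)
        defaults = {"residue": "S", "position": 3, "loc_prob": 0.99}
        for col, val in defaults.items():
            if col not in frame.columns:
                frame[col] = val
        if "site_id" not in frame.columns:
            frame["site_id"] = (frame["protein_id"].astype(str) + "_"
                                + frame["residue"]
                                + frame["position"].astype(str))
        return PhosphoSites(frame, design)
    return _make
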