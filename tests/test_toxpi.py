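import numpy as np
import pandas as pd
import pytest

from uvcblink import toxpi
from uvcblink.bioassay import PODTable


def test_toxpi_endpoints():
    assert toxpi.toxpi_value(1.0, 1.0, 100.0) == pytest.approx(1.0)
    assert toxpi.toxpi_value(100.0, 1.0, 100.0) == pytest.approx(0.0)
    assert toxpi.toxpi_value(10.0, 1.0, 100.0) == pytest.approx(0.5)  # geometric midpoint


def test_toxpi_degenerate_range():
    assert toxpi.toxpi_value(5.0, 5.0, 5.0) == 0.0


def test_toxpi_monotone_decreasing_in_pod():
    vals = [toxpi.toxpi_value(p, 1.0, 1000.0) for p in (1.0, 10.0, 100.0, 1000.0)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def _pods(values: dict[str, dict[str, float]]) -> PODTable:
    rows = [
        (sub, ep, pod, False)
        for ep, by_sub in values.items()
        for sub, pod in by_sub.items()
    ]
    t = pd.DataFrame(rows, columns=["substance_id", "endpoint", "pod", "censored"])
    return PODTable(t, t.groupby("endpoint")["pod"].min(), t.groupby("endpoint")["pod"].max())


def test_celltype_toxpi_slices_and_scores():
    pods = _pods({
        "neuron:ph1": {"A": 1.0, "B": 10.0, "C": 100.0},
        "neuron:ph2": {"A": 1.0, "B": 100.0, "C": 100.0},
        "hep:ph1": {"A": 100.0, "B": 1.0, "C": 100.0},
    })
    profiles = toxpi.celltype_toxpi(pods)
    assert set(profiles) == {"neuron", "hep"}
    neuron = profiles["neuron"]
    # A is most potent on both neuron endpoints -> slice values 1, score 1
    assert neuron.slice_values.loc["A"].tolist() == [1.0, 1.0]
    assert neuron.scores["A"] == pytest.approx(1.0)
    assert neuron.scores["C"] == pytest.approx(0.0)
    # equal weights: B's score is the mean of its two slice values
    assert neuron.scores["B"] == pytest.approx(neuron.slice_values.loc["B"].mean())


def test_overall_toxpi_rescale_bounds():
    ct = pd.DataFrame(
        {"neuron": [1.0, 0.5, 0.1], "hep": [0.2, 0.8, 0.4]},
        index=["A", "B", "C"],
    )
    overall = toxpi.overall_toxpi(ct)
    assert overall.scores.between(0.0, 1.0).all()
    # each rescaled slice spans exactly [0, 1] on the log scale
    sv = overall.slice_values
    assert sv["neuron"].max() == pytest.approx(1.0)
    assert sv["neuron"].min() == pytest.approx(0.0)


def test_overall_toxpi_zero_score_maps_to_zero():
    ct = pd.DataFrame({"neuron": [0.0, 0.5, 1.0]}, index=["A", "B", "C"])
    overall = toxpi.overall_toxpi(ct)
    assert overall.slice_values.loc["A", "neuron"] == 0.0


def test_overall_toxpi_order_preserved_within_slice():
    ct = pd.DataFrame({"neuron": [0.9, 0.5, 0.1], "hep": [0.9, 0.5, 0.1]},
                      index=["A", "B", "C"])
    overall = toxpi.overall_toxpi(ct)
    s = overall.scores
    assert s["A"] > s["B"] > s["C"]
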