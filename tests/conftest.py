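import datetime as dt

import pandas as pd
import pytest

from collabnet.network import CollaborationNetwork


def net_from_edges(edges, isolated=(), specialty="x"):
    """Build a small network from an iterable of (a, b, w) triples."""
    nodes = {u: specialty for u in isolated}
    emap = {}
    for a, b, w in edges:
        key = tuple(sorted((a, b)))
        emap[key] = int(w)
        nodes[a] = specialty
        nodes[b] = specialty
    return CollaborationNetwork("", nodes, emap)


@pytest.fixture
def path3():
    return net_from_edges([("a", "b", 1), ("b", "c", 1)])


@pytest.fixture
def star4():
    return net_from_edges([("hub", leaf, 1) for leaf in ("l1", "l2", "l3")])


@pytest.fixture
def triangle():
    return net_from_edges([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])


@pytest.fixture
def k4():
    names = ["a", "b", "c", "d"]
    return net_from_edges(
        [(u, v, 1) for i, u in enumerate(names) for v in names[i + 1:]]
    )


@pytest.fixture
def cycle4():
    return net_from_edges(
        [("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("a", "d", 1)]
    )


def units_frame(triples):
    """Patient-day frame from (clinician, patient, day-number) triples."""
    base = dt.date(2019, 9, 1)
    return pd.DataFrame(
        {
            "clinician_id": [t[0] for t in triples],
            "patient_id": [t[1] for t in triples],
            "day": [base + dt.timedelta(days=t[2]) for t in triples],
        }
    )


@pytest.fixture
def events_csv(tmp_path):
    """A small well-formed events file on disk."""
    path = tmp_path / "events.csv"
    path.write_text(
        "clinician_id,specialty,patient_id,timestamp,action_category\n"
        "n1,nicu_nurse,p1,2019-09-03T08:00:00,note\n"
        "n1,nicu_nurse,p1,2019-09-03T09:30:00,medication\n"
        "d1,neonatologist,p1,2019-09-03T10:00:00,order\n"
        "n2,nicu_nurse,p2,2019-12-31T23:00:00,measurement\n"
    )
    return path
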