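"""YAML model-spec files.

A model spec holds the branching process in sparse triplet form and,
optionally, the full CTMC and a fitted generalised gamma block::

    m: 2
    discrete: false
    nu: [0.0, 0.33]
    alpha:                  # [i, j, rate]
      - [1, 2, 0.5]
    beta:                   # [i, k, l, rate]
      - [2, 1, 2, 0.56]
    ctmc:
      scale: 1000000.0
      x0: [999999, 1, 0]
      events:
        - {delta: [-1, 1, 0], coeff: 5.6e-07, orders: [1, 0, 1], name: exposure}
    gg_fit: {gg_scale: 2.1, gg_shape1: 1.0, gg_shape2: 1.0}

Indices in the file are 1-based (matching the subscripts used throughout
the model descriptions); in-memory arrays are 0-based.
"""

from __future__ import annotations

import numpy as np
import yaml

from .branching import BranchingModel
from .ctmc import CTMCModel, Event
from .mm import GGParams


def model_to_dict(model: BranchingModel, ctmc: CTMCModel | None = None,
                  gg: GGParams | None = None) -> dict:
    m = model.m
    d = {
        "m": m,
        "discrete": bool(model.discrete),
        "nu": [float(x) for x in model.nu],
        "alpha": [
            [i + 1, j + 1, float(model.alpha[i, j])]
            for i in range(m)
            for j in range(m)
            if model.alpha[i, j] != 0
        ],
        "beta": [
            [i + 1, k + 1, l + 1, float(model.beta[i, k, l])]
            for i in range(m)
            for k in range(m)
            for l in range(k, m)
            if model.beta[i, k, l] != 0
        ],
    }
    if ctmc is not None:
        d["ctmc"] = {
            "scale": float(ctmc.scale),
            "x0": [int(x) for x in ctmc.x0],
            "species": list(ctmc.species),
            "events": [
                {
                    "delta": [int(v) for v in e.delta],
                    "coeff": float(e.coeff),
                    "orders": [int(v) for v in e.orders],
                    "name": e.name,
                }
                for e in ctmc.events
            ],
        }
    if gg is not None:
        d["gg_fit"] = {
            "gg_scale": float(gg.gg_scale),
            "gg_shape1": float(gg.gg_shape1),
            "gg_shape2": float(gg.gg_shape2),
        }
    return d


def dict_to_model(d: dict):
    m = int(d["m"])
    nu = np.asarray(d.get("nu", np.zeros(m)), dtype=float)
    alpha = np.zeros((m, m))
    for i, j, rate in d.get("alpha", []):
        alpha[int(i) - 1, int(j) - 1] += float(rate)
    beta = np.zeros((m, m, m))
    for i, k, l, rate in d.get("beta", []):
        beta[int(i) - 1, int(k) - 1, int(l) - 1] += float(rate)
    model = BranchingModel(nu, alpha, beta, discrete=bool(d.get("discrete", False)))
    ctmc = None
    if "ctmc" in d:
        c = d["ctmc"]
        ctmc = CTMCModel(
            events=[
                Event(e["delta"], float(e["coeff"]), e["orders"], e.get("name", ""))
                for e in c["events"]
            ],
            scale=float(c["scale"]),
            x0=np.asarray(c["x0"], dtype=int),
            species=list(c.get("species", [])),
        )
    gg = None
    if "gg_fit" in d:
        g = d["gg_fit"]
        gg = GGParams(g["gg_scale"], g["gg_shape1"], g["gg_shape2"])
    return model, ctmc, gg


def save_model(path, model: BranchingModel, ctmc: CTMCModel | None = None,
               gg: GGParams | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model, ctmc, gg), fh, sort_keys=False)


def load_model(path):
    """Returns (BranchingModel, CTMCModel | None, GGParams | None)."""
    with open(path) as fh:
        return dict_to_model(yaml.safe_load(fh))
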