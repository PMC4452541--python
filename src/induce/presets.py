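"""Named example parameterizations of the motif library.

These are the package's reference conditions: a two-channel assay over a
23-point logarithmic dose grid at 10⁴ cells per dose (the scale of a
flow-cytometry dose-response experiment), with intrinsic log-noise
magnitudes giving log-variances of a few percent — the order observed
for fluorescent-reporter and phosphoprotein readouts.  One
parameterization is provided per qualitative regime:

* ``two_node_activation`` / ``two_node_repression`` — an isolated edge
  whose connection strength is swept through its full range by the dose;
  the variance-vs-covariance path is a single-valued quadratic.
* ``two_node_null`` — the severed-edge (k = 0) control: the target is
  produced at a constant rate, species are independent at every dose.
* ``convergent`` — two regulators of the target with disparate dose
  sensitivities; their noise sources interact and the path opens a loop.
* ``cascade`` — a three-species relay whose upstream noise propagates
  two hops with disparate sensitivities, again opening a loop.
"""

from __future__ import annotations

import numpy as np

from induce.errors import InputError
from induce.motif_models import ConstantTransfer, HillTransfer, MotifSpec
from induce.synthetic_data import DoseDesign

#: default dose grid: 23 log-spaced doses spanning the drive's dynamic range
DEFAULT_DOSES = tuple(np.geomspace(0.01, 100.0, 23))

#: default cells per dose (flow-cytometry scale)
DEFAULT_N_CELLS = 10_000

_PRESETS = {
    "two_node_activation": dict(
        motif=dict(
            kind="two_node", lambdas=[1.0, 1.0], qs=[0.45, 0.20],
            edges={(0, 1): HillTransfer(nu=5.0, K=1.0, n=2.0)},
        ),
        drive={0: HillTransfer(nu=10.0, K=1.0, n=1.0)},
    ),
    "two_node_repression": dict(
        motif=dict(
            kind="two_node", lambdas=[1.0, 1.0], qs=[0.45, 0.20],
            edges={(0, 1): HillTransfer(nu=5.0, K=1.0, n=2.0, repression=True)},
        ),
        drive={0: HillTransfer(nu=10.0, K=1.0, n=1.0)},
    ),
    "two_node_null": dict(
        motif=dict(
            kind="two_node", lambdas=[1.0, 1.0], qs=[0.45, 0.20],
            edges={(0, 1): ConstantTransfer(level=2.0)},
        ),
        drive={0: HillTransfer(nu=10.0, K=1.0, n=1.0)},
    ),
    "convergent": dict(
        motif=dict(
            kind="convergent", lambdas=[1.0, 1.0, 1.0], qs=[0.40, 0.15, 0.50],
            edges={
                (0, 1): HillTransfer(nu=5.0, K=1.0, n=2.0),
                (2, 1): HillTransfer(nu=5.0, K=1.0, n=2.0),
            },
        ),
        drive={
            0: HillTransfer(nu=10.0, K=0.3, n=2.0),
            2: HillTransfer(nu=10.0, K=30.0, n=2.0),
        },
    ),
    # upstream gain falls while the (repressive) downstream gain rises as
    # dose increases: the opposed sweeps make both variance-vs-covariance
    # planes revisit covariances at different variances (open loops)
    "cascade": dict(
        motif=dict(
            kind="cascade", lambdas=[1.0, 1.0, 1.0], qs=[0.10, 0.15, 0.80],
            edges={
                (2, 0): HillTransfer(nu=5.0, K=1.0, n=2.0),
                (0, 1): HillTransfer(nu=5.0, K=4.0, n=2.0, repression=True),
            },
        ),
        drive={2: HillTransfer(nu=10.0, K=1.0, n=1.0)},
    ),
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def example_motif(name: str) -> MotifSpec:
    """A named example motif (fresh instance)."""
    try:
        spec = _PRESETS[name]["motif"]
    except KeyError:
        raise InputError(
            f"unknown preset {name!r}; available: {preset_names()}"
        ) from None
    return MotifSpec(kind=spec["kind"], lambdas=list(spec["lambdas"]),
                     qs=list(spec["qs"]), edges=dict(spec["edges"]))


def example_drive(name: str) -> dict[int, object]:
    """The dose → root-mean drive paired with a named motif."""
    if name not in _PRESETS:
        raise InputError(f"unknown preset {name!r}; available: {preset_names()}")
    return dict(_PRESETS[name]["drive"])


def example_design(
    name: str,
    n_cells: int = DEFAULT_N_CELLS,
    seed: int = 0,
    doses=None,
) -> tuple[MotifSpec, DoseDesign]:
    """Motif plus matching dose design for a named preset."""
    m = example_motif(name)
    d = DoseDesign(
        doses=list(DEFAULT_DOSES) if doses is None else list(doses),
        upstream_drive=example_drive(name),
        n_cells=n_cells,
        seed=seed,
    )
    return m, d
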