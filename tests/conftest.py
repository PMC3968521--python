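"""Shared fixtures: the calibrated default network, its flow solution, and
small hand-built tube networks (straight run, symmetric Y, symmetric H)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import emboflow as ef

hyp_settings.register_profile("repro", derandomize=True, deadline=None)
hyp_settings.load_profile("repro")
from emboflow.vasculature import NetworkNode, VesselSegment, VascularNetwork


@pytest.fixture(scope="session")
def fluid():
    return ef.FluidProperties()


@pytest.fixture(scope="session")
def default_network(fluid):
    """Complete-variant network, inlets extended, terminals calibrated."""
    net = ef.extend_inlets(ef.generate_cow(ef.CoWVariantSpec()), 10.0)
    return ef.calibrate_terminals(net, fluid).network


@pytest.fixture(scope="session")
def default_solution(default_network, fluid):
    return ef.solve_flow(default_network, fluid, ef.BoundarySpec.default(default_network))


@pytest.fixture(scope="session")
def b2_core_records(default_network, default_solution, fluid):
    """One medium-size, near-neutral-density core-release run, shared by
    metrics and invariant tests."""
    proto = ef.ReleaseProtocol(mode="core", window=34)
    cfg = ef.SimConfig(seed=7)
    return ef.run(
        default_network, default_solution, ef.case_spec("B2"), proto, cfg, fluid, case="B2"
    )


def make_straight_tube(length_mm=100.0, radius_mm=2.0):
    """Straight tube along +x split into an inlet half and a terminal half."""
    half = length_mm / 2.0
    nodes = [
        NetworkNode("IN_n", np.array([0.0, 0.0, 0.0]), "inlet"),
        NetworkNode("J", np.array([half, 0.0, 0.0]), "junction"),
        NetworkNode("OUT_n", np.array([length_mm, 0.0, 0.0]), "outlet"),
    ]
    segs = [
        VesselSegment("IN", np.array([[0.0, 0, 0], [half, 0, 0]]), radius_mm,
                      "IN_n", "J", "FEEDING", "inlet"),
        VesselSegment("OUT", np.array([[half, 0, 0], [length_mm, 0, 0]]), radius_mm,
                      "J", "OUT_n", "MCA_R", "terminal"),
    ]
    net = VascularNetwork(nodes, segs, name="straight_tube")
    net.validate()
    return net


def make_symmetric_y(radius_mm=1.5):
    """One inlet splitting into two mirror-image daughters."""
    nodes = [
        NetworkNode("IN_n", np.array([0.0, 0.0, 0.0]), "inlet"),
        NetworkNode("J", np.array([20.0, 0.0, 0.0]), "junction"),
        NetworkNode("UP_n", np.array([40.0, 15.0, 0.0]), "outlet"),
        NetworkNode("DN_n", np.array([40.0, -15.0, 0.0]), "outlet"),
    ]
    segs = [
        VesselSegment("IN", np.array([[0.0, 0, 0], [20.0, 0, 0]]), radius_mm * 1.3,
                      "IN_n", "J", "FEEDING", "inlet"),
        VesselSegment("UP", np.array([[20.0, 0, 0], [40.0, 15, 0]]), radius_mm,
                      "J", "UP_n", "MCA_L", "terminal"),
        VesselSegment("DN", np.array([[20.0, 0, 0], [40.0, -15, 0]]), radius_mm,
                      "J", "DN_n", "MCA_R", "terminal"),
    ]
    net = VascularNetwork(nodes, segs, name="symmetric_y")
    net.validate()
    return net


def make_symmetric_h(n_crossbars=2):
    """Two parallel inlet->outlet runs joined by crossbars that carry no
    flow by symmetry (two parallel communicating edges, so one can be
    removed while the graph stays connected)."""
    nodes = [
        NetworkNode("A_in", np.array([0.0, 0.0, 0.0]), "inlet"),
        NetworkNode("B_in", np.array([0.0, 30.0, 0.0]), "inlet"),
        NetworkNode("J1", np.array([20.0, 0.0, 0.0]), "junction"),
        NetworkNode("J2", np.array([20.0, 30.0, 0.0]), "junction"),
        NetworkNode("A_out", np.array([50.0, 0.0, 0.0]), "outlet"),
        NetworkNode("B_out", np.array([50.0, 30.0, 0.0]), "outlet"),
    ]
    segs = [
        VesselSegment("A_IN", np.array([[0.0, 0, 0], [20.0, 0, 0]]), 2.0,
                      "A_in", "J1", "FEEDING", "inlet"),
        VesselSegment("B_IN", np.array([[0.0, 30, 0], [20.0, 30, 0]]), 2.0,
                      "B_in", "J2", "FEEDING", "inlet"),
        VesselSegment("A_OUT", np.array([[20.0, 0, 0], [50.0, 0, 0]]), 1.5,
                      "J1", "A_out", "MCA_R", "terminal"),
        VesselSegment("B_OUT", np.array([[20.0, 30, 0], [50.0, 30, 0]]), 1.5,
                      "J2", "B_out", "MCA_L", "terminal"),
    ]
    if n_crossbars >= 1:
        segs.append(
            VesselSegment("XBAR1", np.array([[20.0, 0, 0], [20.0, 30, 0]]), 1.0,
                          "J1", "J2", "COMMUNICATING", "internal")
        )
    if n_crossbars >= 2:
        segs.append(
            VesselSegment("XBAR2", np.array([[20.0, 0, 0], [26.0, 15, 0], [20.0, 30, 0]]),
                          1.0, "J1", "J2", "COMMUNICATING", "internal")
        )
    net = VascularNetwork(nodes, segs, name="symmetric_h")
    net.validate()
    return net
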