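"""EMU decomposition and simulation against the isotopomer oracle."""

import numpy as np
import pytest

from edflux import emu, isotopes, synth
from edflux.model import TracerInputSpec, model_from_dict, split_reversible


def _chain_model(reversible=False):
    """X -> A -> B linear chain with 2 traced atoms."""
    doc = {
        "element": "C",
        "metabolites": [
            {"name": "X", "formula": "C2H4O2", "traced": ["C1", "C2"], "role": "substrate_input"},
            {"name": "A", "formula": "C2H4O2", "traced": ["C1", "C2"]},
            {"name": "B", "formula": "C2H4O2", "traced": ["C1", "C2"]},
            {"name": "OUT", "formula": "C2H4O2", "traced": ["C1", "C2"], "role": "sink_output"},
        ],
        "reactions": [
            {"id": "R1", "equation": "X (ab) -> A (ab)"},
            {"id": "R2", "equation": "A (ab) -> B (ab)", "reversible": reversible},
            {"id": "R3", "equation": "B (ab) -> OUT (ab)"},
        ],
        "observations": ["A", "B"],
    }
    return split_reversible(model_from_dict(doc))


def _pure_tracer(positions, met="X"):
    """Fully defined tracer with no unlabeled admixture."""
    return TracerInputSpec(met, [(tuple(positions), 1.0)])


class TestDecomposition:
    def test_linear_chain_identity_cascade(self):
        model = _chain_model()
        net = emu.decompose_emus(model)
        emus = [e for _, level_emus, _ in net.levels for e in level_emus]
        assert set(emus) == {
            emu.EMU("A", (0, 1)),
            emu.EMU("B", (0, 1)),
        }
        assert [size for size, _, _ in net.levels] == [2]

    def test_eda_cleavage_pulls_correct_fragments(self, split_models):
        net = emu.decompose_emus(split_models["C"], targets=["PYR", "GAP"])
        defs = {e: terms for _, _, level in net.levels for e, terms in level.items()}
        gap_terms = defs[emu.EMU("GAP", (0, 1, 2))]
        eda_pieces = [
            t.pieces for t in gap_terms if net.rxn_ids[t.rxn_index] == "EDA"
        ]
        assert eda_pieces == [[emu.EMU("KDPG", (3, 4, 5))]]
        pyr_terms = defs[emu.EMU("PYR", (0, 1, 2))]
        eda_pyr = [t.pieces for t in pyr_terms if net.rxn_ids[t.rxn_index] == "EDA"]
        assert eda_pyr == [[emu.EMU("KDPG", (0, 1, 2))]]

    def test_condensation_creates_convolution_node(self):
        model, fluxes, tracer = synth.random_toy_network(0)
        net = emu.decompose_emus(model, targets=["D"])
        defs = {e: terms for _, _, level in net.levels for e, terms in level.items()}
        d_terms = defs[emu.EMU("D", (0, 1, 2, 3))]
        (r3_term,) = [t for t in d_terms if net.rxn_ids[t.rxn_index] == "R3"]
        assert len(r3_term.pieces) == 2  # B-piece and C-piece convolved

    def test_target_without_traced_atoms_rejected(self, split_models):
        with pytest.raises(Exception, match="traced"):
            emu.decompose_emus(split_models["C"], targets=["REDH"])


class TestSimulation:
    def test_chain_passes_input_through(self):
        model = _chain_model()
        net = emu.decompose_emus(model)
        fluxes = {"R1": 10.0, "R2": 10.0, "R3": 10.0}
        mids = emu.simulate_mids(net, fluxes, {"X": _pure_tracer(["C1"])})
        nat = isotopes.heavy_fraction("C")
        expected = np.convolve([0.0, 1.0], [1 - nat, nat])
        np.testing.assert_allclose(mids["B"].fractions, expected, atol=1e-12)

    def test_fully_labeled_input_fully_labels_chain(self):
        model = _chain_model()
        net = emu.decompose_emus(model)
        fluxes = {"R1": 1.0, "R2": 1.0, "R3": 1.0}
        mids = emu.simulate_mids(net, fluxes, {"X": _pure_tracer(["C1", "C2"])})
        np.testing.assert_allclose(mids["A"].fractions, [0, 0, 1], atol=1e-12)

    def test_convolution_of_two_binary_emus(self):
        """Condensing two half-labeled 1-atom units gives [1/4, 1/2, 1/4]."""
        a = np.array([0.5, 0.5])
        assert np.allclose(np.convolve(a, a), [0.25, 0.5, 0.25])
        # and through a real condensation network
        doc = {
            "element": "C",
            "metabolites": [
                {"name": "X", "formula": "CH2O", "traced": ["C1"], "role": "substrate_input"},
                {"name": "Y", "formula": "CH2O", "traced": ["C1"], "role": "substrate_input"},
                {"name": "Z", "formula": "C2H4O2", "traced": ["C1", "C2"]},
                {"name": "OUT", "formula": "C2H4O2", "traced": ["C1", "C2"], "role": "sink_output"},
            ],
            "reactions": [
                {"id": "R1", "equation": "X (a) + Y (b) -> Z (ab)"},
                {"id": "R2", "equation": "Z (ab) -> OUT (ab)"},
            ],
            "observations": ["Z"],
        }
        model = model_from_dict(doc)
        net = emu.decompose_emus(model)
        tracers = {
            "X": TracerInputSpec("X", [(("C1",), 0.5), ((), 0.5)]),
            "Y": TracerInputSpec("Y", [(("C1",), 0.5), ((), 0.5)]),
        }
        mids = emu.simulate_mids(net, {"R1": 1.0, "R2": 1.0}, tracers)
        nat = isotopes.heavy_fraction("C")
        one = np.array([0.5 * (1 - nat), 0.5 + 0.5 * nat])
        np.testing.assert_allclose(mids["Z"].fractions, np.convolve(one, one), atol=1e-12)

    def test_unbalanced_fluxes_rejected(self):
        model = _chain_model()
        net = emu.decompose_emus(model)
        with pytest.raises(emu.EmuError, match="steady state"):
            emu.simulate_mids(net, {"R1": 10.0, "R2": 5.0, "R3": 10.0}, {"X": _pure_tracer(["C1"])})

    def test_negative_flux_rejected(self):
        model = _chain_model()
        net = emu.decompose_emus(model)
        with pytest.raises(emu.EmuError, match="negative"):
            emu.simulate_mids(net, {"R1": 1.0, "R2": -1.0, "R3": 1.0}, {"X": _pure_tracer([])})


class TestOracleAgreement:
    @pytest.mark.parametrize("element,tracer", [("C", "1-13C"), ("C", "6-13C"), ("H", "4-2H"), ("H", "5-2H")])
    @pytest.mark.parametrize("condition", ["n2", "nh4"])
    def test_shipped_fixtures_match_enumeration(
        self, models, split_models, emunets, element, tracer, condition
    ):
        if synth.TRACERS[tracer][0] != element:
            pytest.skip("tracer/element pairing")
        truth = synth.make_truth(condition)
        fluxes = synth.truth_fluxes(truth, models[element])
        spec = synth.make_tracer(tracer, 0.01)
        fast = emu.simulate_mids(emunets[element], fluxes, {"GLC.ext": spec})
        slow = emu.enumerate_isotopomers(split_models[element], fluxes, {"GLC.ext": spec})
        for met in fast:
            np.testing.assert_allclose(
                fast[met].fractions, slow[met].fractions, atol=1e-9
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_random_networks_match_enumeration(self, seed):
        model, fluxes, tracer = synth.random_toy_network(seed)
        net = emu.decompose_emus(model)
        fast = emu.simulate_mids(net, fluxes, {"X": tracer})
        slow = emu.enumerate_isotopomers(model, fluxes, {"X": tracer})
        for met in fast:
            np.testing.assert_allclose(fast[met].fractions, slow[met].fractions, atol=1e-9)

    def test_exchange_pulls_mid_toward_partner(self, models):
        """Raising EDA exchange moves KDPG toward the recombination MID.

        Under [6-13C] glucose the reverse-flux marker KDPG M+2 must grow
        monotonically with the exchange flux.
        """
        tracer = synth.make_tracer("6-13C", 0.01)
        m = models["C"]
        net = emu.decompose_emus(split_reversible(m))
        m2 = []
        for dg in (-8.0, -4.0, -2.0, -1.0, -0.5):
            truth = synth.make_truth("n2", overrides={"EDA": dg})
            fluxes = synth.truth_fluxes(truth, m)
            mids = emu.simulate_mids(net, fluxes, {"GLC.ext": tracer})
            m2.append(mids["KDPG"].fractions[2])
        assert all(a < b for a, b in zip(m2, m2[1:]))

    def test_atom_letter_relabeling_invariant(self):
        doc_template = {
            "element": "C",
            "metabolites": [
                {"name": "X", "formula": "C3H6O3", "traced": ["C1", "C2", "C3"], "role": "substrate_input"},
                {"name": "A", "formula": "C3H6O3", "traced": ["C1", "C2", "C3"]},
                {"name": "OUT", "formula": "C3H6O3", "traced": ["C1", "C2", "C3"], "role": "sink_output"},
            ],
            "reactions": [
                {"id": "R1", "equation": None},
                {"id": "R2", "equation": "A (abc) -> OUT (abc)"},
            ],
            "observations": ["A"],
        }
        tracer = TracerInputSpec("X", [(("C1", "C3"), 0.7), ((), 0.3)])
        results = []
        for eqn in ("X (abc) -> A (cab)", "X (xyz) -> A (zxy)"):
            doc = {**doc_template, "reactions": [
                {"id": "R1", "equation": eqn},
                {"id": "R2", "equation": "A (abc) -> OUT (abc)"},
            ]}
            model = model_from_dict(doc)
            net = emu.decompose_emus(model)
            mids = emu.simulate_mids(net, {"R1": 1.0, "R2": 1.0}, {"X": tracer})
            results.append(mids["A"].fractions)
        np.testing.assert_array_equal(results[0], results[1])


class TestUntracedConvolution:
    def test_zero_untraced_atoms_is_identity(self):
        mid = np.array([0.2, 0.8])
        out = emu.convolve_untraced_atoms(mid, {"C": 1}, "C", 1, extra_bins=1)
        np.testing.assert_allclose(out[:2], mid, atol=1e-12)

    def test_two_untraced_carbons_binomial(self):
        """Two natural carbons on an M+0 ion give the 13C binomial."""
        mid = np.array([1.0])
        out = emu.convolve_untraced_atoms(mid, {"C": 2}, "C", 0, extra_bins=2)
        p = 0.0107
        expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        np.testing.assert_allclose(out, expected, atol=5e-5)
        np.testing.assert_allclose(out, [0.97871, 0.02117, 0.00011], atol=5e-6)

    def test_formula_traced_inconsistency_rejected(self):
        with pytest.raises(ValueError, match="traced"):
            emu.convolve_untraced_atoms(np.array([1.0, 0.0]), {"C": 1}, "C", 2)

    def test_normalization_preserved(self, models, emunets):
        truth = synth.make_truth("n2")
        fluxes = synth.truth_fluxes(truth, models["C"])
        mids = emu.simulate_mids(emunets["C"], fluxes, {"GLC.ext": synth.make_tracer("1-13C")})
        for met, mid in mids.items():
            spec = models["C"].metabolites[met]
            out = emu.convolve_untraced_atoms(mid.fractions, spec.formula, "C", spec.n_traced)
            assert abs(out.sum() - 1.0) < 1e-12
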