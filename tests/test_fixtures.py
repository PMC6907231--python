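import pytest

from chemscan.errors import ChemScanError
from chemscan.fixtures import (
    SchemeSpec,
    StepSpec,
    compare_to_truth,
    generate_scheme,
    generate_scheme_cdx,
    random_spec,
    wrap_in_container,
)
from chemscan.pipeline import scan_bytes


class TestDeterminism:
    def test_same_seed_same_bytes(self):
        spec = random_spec(21)
        assert generate_scheme(spec)[0] == generate_scheme(spec)[0]
        assert generate_scheme_cdx(spec)[0] == generate_scheme_cdx(spec)[0]

    def test_container_wrapping_deterministic(self):
        cdx, _ = generate_scheme_cdx(random_spec(22, jitter=0.0))
        assert wrap_in_container(cdx, "docx") == wrap_in_container(cdx, "docx")
        assert wrap_in_container(cdx, "doc") == wrap_in_container(cdx, "doc")


class TestGenerateScheme:
    def test_three_step_wrapped_chain_has_three_arrows(self):
        spec = SchemeSpec(steps=[
            StepSpec(reactants=["CCO"], product="CC=O"),
            StepSpec(reactants=["CC=O"], product="CC(=O)O"),
            StepSpec(reactants=["CC(=O)O"], product="CCOC(C)=O"),
        ], layout="wrapped-chain", jitter=0.0)
        cdxml, _ = generate_scheme(spec)
        assert cdxml.count("<arrow") == 3

    def test_zero_jitter_extracts_exactly(self, libs):
        spec = random_spec(30, jitter=0.0)
        cdxml, truth = generate_scheme(spec)
        result = scan_bytes(cdxml.encode(), "z", libs=libs)[0]
        assert compare_to_truth(result.steps, truth) == []

    def test_unparsable_smiles_in_spec_is_error(self):
        spec = SchemeSpec(steps=[StepSpec(reactants=["]["], product="CCO")])
        with pytest.raises((ChemScanError, ValueError)):
            generate_scheme(spec)


class TestRandomSpec:
    def test_valid_spec(self):
        spec = random_spec(1, pool=["CCO", "CC=O", "CCN", "c1ccccc1",
                                    "CC(C)=O"])
        assert 1 <= len(spec.steps) <= 4
        for step in spec.steps:
            assert step.reactants and step.product

    def test_seed_diversity(self):
        """Different seeds give (almost always) different specs."""
        seen = {repr(random_spec(s)) for s in range(1, 101)}
        assert len(seen) >= 99

    def test_max_steps_one(self):
        assert len(random_spec(7, max_steps=1).steps) == 1

    def test_empty_pool_rejected(self):
        with pytest.raises(ChemScanError):
            random_spec(1, pool=[])

    def test_styles_sampled_beyond_plain(self):
        styles = {step.arrow_style for s in range(1, 60)
                  for step in random_spec(s).steps}
        assert {"plain", "dashed", "crossed"} <= styles


class TestAdversarialPlacement:
    """Objects near zone boundaries: extraction must stay deterministic even
    when correctness is not guaranteed."""

    def test_boundary_jitter_is_deterministic(self, libs):
        spec = random_spec(33)
        spec = SchemeSpec(steps=spec.steps, layout=spec.layout,
                          jitter=0.35, seed=spec.seed)
        cdxml1, _ = generate_scheme(spec)
        cdxml2, _ = generate_scheme(spec)
        assert cdxml1 == cdxml2
        out1 = scan_bytes(cdxml1.encode(), "a", libs=libs)[0]
        out2 = scan_bytes(cdxml2.encode(), "a", libs=libs)[0]
        key = lambda r: [(sorted(m.cano_smiles for m in s.reactants),
                          sorted(m.cano_smiles for m in s.products),
                          s.status) for s in r.steps]
        assert key(out1) == key(out2)


def test_wrap_unknown_kind():
    with pytest.raises(ChemScanError):
        wrap_in_container(b"x", "pptx")
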