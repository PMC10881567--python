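import pytest

import fuzzydx as fx


@pytest.fixture(scope="session")
def registry():
    return fx.PartitionRegistry.default()


@pytest.fixture(scope="session")
def schema():
    return fx.FeatureSchema.default()


@pytest.fixture(scope="session")
def taxonomy():
    return fx.generate_fixture_taxonomy()


@pytest.fixture(scope="session")
def core_rb(registry):
    return fx.core_rulebase(registry)


@pytest.fixture(scope="session")
def rulebase(registry):
    return fx.default_rulebase(registry)


def run_engine_on_description(system: dict, crisp: dict, resolution: int):
    """Drive the package's full pipeline over an oracle-style system dict.

    Returns the diagnosis value, or None when no rule fires.
    """
    registry = fx.PartitionRegistry()
    for name, var in system["inputs"].items():
        registry.add(
            fx.LinguisticVariable(
                name=name,
                domain=var["domain"],
                labels=tuple(var["sets"]),
                sets={
                    label: fx.MembershipFunction(shape, pts)
                    for label, (shape, pts) in var["sets"].items()
                },
            )
        )
    out_var = fx.LinguisticVariable(
        name="DR",
        domain=system["output"]["domain"],
        labels=tuple(system["out_order"]),
        sets={
            label: fx.MembershipFunction(shape, pts)
            for label, (shape, pts) in system["output"]["sets"].items()
        },
    )
    registry.add(out_var)
    rules = [
        fx.FuzzyRule(
            id=f"r{i}",
            antecedent=tuple(fx.RuleAtom(var, label) for var, label in atoms),
            consequent=out_label,
        )
        for i, (atoms, out_label) in enumerate(system["rules"])
    ]
    rb = fx.RuleBase(rules=rules, registry=registry)
    fuzzified = {
        name: fx.fuzzify(registry.get(name), value) for name, value in crisp.items()
    }
    activations, _ = fx.evaluate(rb, fuzzified)
    out_set = fx.aggregate_outputs(activations, out_var)
    try:
        return fx.defuzzify_cog(out_set, resolution=resolution), dict(out_set.activations)
    except fx.EmptyOutput:
        return None, dict(out_set.activations)


@pytest.fixture()
def emci_like_record():
    """Numerics sitting at the EMCI prototype peaks, mood-branch symptoms."""
    return fx.PatientRecord(
        id="p1",
        features={
            "FDG": 1.0,
            "Hippocampus": 5200,
            "MidTemp": 17000,
            "MMSE": 22,
            "CDRSB": 2.5,
            "LDELTOTAL": 13,
        },
        symptoms=("anxious", "depressed", "fearful"),
        complications=("arterial hypertension", "osteoarthritis"),
    )
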