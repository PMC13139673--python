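import numpy as np
import pytest

from structassess import (
    SiteDefinition,
    aggregate_global_mean,
    orthosteric_site,
    rank_site_residues,
    residue_confidence,
    site_confidence,
)
from structassess import synthetic as syn
from structassess.confidence import SiteConfidenceReport
from structassess.model import Atom, Chain, Residue, StructureModel

from conftest import (
    AF2_ALLOSTERIC,
    AF2_ALLOSTERIC_GLOBAL,
    AF2_ORTHOSTERIC,
    AF2_ORTHOSTERIC_GLOBAL,
    AF3_ALLOSTERIC,
    AF3_ORTHOSTERIC,
    AF3_ORTHOSTERIC_GLOBAL,
)


def _one_residue_model(bvalues, number=1, aa="A"):
    atoms = [
        Atom(name=f"C{i}" if i else "CA", element="C", coords=np.array([float(i), 0, 0]), bvalue=b)
        for i, b in enumerate(bvalues)
    ]
    chain = Chain(id="A", residues=[Residue(number=number, aa_code=aa, atoms=atoms)])
    return StructureModel(id="toy", chains=[chain])


def test_atom_mean_of_two_values():
    cmap = residue_confidence(_one_residue_model([80.0, 90.0]), mode="atom_mean")
    assert cmap[("A", 1)] == pytest.approx(85.0)


def test_residue_level_files_agree_between_modes():
    model = _one_residue_model([77.73, 77.73, 77.73])
    for mode in ("atom_mean", "ca_only"):
        assert residue_confidence(model, mode=mode)[("A", 1)] == pytest.approx(77.73)


def test_planted_noise_means_match_generator_exactly():
    spec = syn.FixtureSpec(
        seed=7, n_residues=30,
        confidence=syn.ConfidenceProfile(base=77.5, atom_noise_sigma=8.0),
    )
    model, truth = syn.make_trimer(spec)
    cmap = residue_confidence(model)
    for key, expected in truth.residue_means.items():
        assert cmap[key] == pytest.approx(expected, abs=1e-9)


def test_experimental_models_refuse_confidence():
    model = _one_residue_model([30.0])
    model.metadata["experimental"] = True
    with pytest.raises(ValueError, match="experimental"):
        residue_confidence(model)


def _planted_site_model(values: dict[int, float], aa_ok=True):
    """Trimer with the given per-residue pLDDT planted at those residues."""
    spec = syn.FixtureSpec(
        seed=0, n_residues=max(values) + 10,
        confidence=syn.ConfidenceProfile(base=80.0, sitewise=dict(values)),
    )
    model, truth = syn.make_trimer(spec)
    return model, truth


def _site_for(values: dict[int, float], offsets=()):
    return SiteDefinition("site", [(n, "A") for n in sorted(values)], tuple(offsets))


def test_af2_orthosteric_global_average_from_planted_profile():
    """Planting the published per-residue means reproduces the published
    site global average of 89.23."""
    model, _ = _planted_site_model(AF2_ORTHOSTERIC)
    report = site_confidence(
        residue_confidence(model), model, _site_for(AF2_ORTHOSTERIC)
    )
    assert round(report.global_average, 2) == AF2_ORTHOSTERIC_GLOBAL
    for (label, value), (number, expected) in zip(
        report.per_residue, sorted(AF2_ORTHOSTERIC.items())
    ):
        assert value == pytest.approx(expected, abs=1e-9)


def test_uniform_model_gives_uniform_report():
    spec = syn.FixtureSpec(seed=0, n_residues=40, confidence=syn.ConfidenceProfile(base=50.0))
    model, _ = syn.make_trimer(spec)
    site = SiteDefinition("s", [(15, "A"), (20, "A")], (-3, -2, -1, 1, 2))
    report = site_confidence(residue_confidence(model), model, site)
    assert all(v == pytest.approx(50.0) for _, v in report.per_residue)
    assert report.global_average == pytest.approx(50.0)


def test_windowed_report_matches_generator_expectation():
    spec = syn.FixtureSpec(
        seed=13, n_residues=60,
        confidence=syn.ConfidenceProfile(base=75.0, atom_noise_sigma=6.0),
    )
    model, truth = syn.make_trimer(spec)
    offsets = (-3, -2, -1, 1, 2)
    numbers = [5, 17, 30, 58]  # includes residues near both termini
    site = SiteDefinition("s", [(n, "A") for n in numbers], offsets)
    report = site_confidence(residue_confidence(model), model, site)
    expected_per_res, expected_global = truth.site_expectation(
        numbers, offsets, [c.id for c in model.chains]
    )
    for (_, got), want in zip(report.per_residue, expected_per_res):
        assert got == pytest.approx(want, abs=1e-9)
    assert report.global_average == pytest.approx(expected_global, abs=1e-9)


def test_empty_offsets_equal_raw_confidence_values(trimer):
    model, truth = trimer
    site = SiteDefinition("s", [(25, "A")], ())
    report = site_confidence(residue_confidence(model), model, site)
    raw = np.mean([truth.residue_means[(c.id, 25)] for c in model.chains])
    assert report.per_residue[0][1] == pytest.approx(raw, abs=1e-9)


def test_window_clipping_at_termini_does_not_raise(trimer):
    model, _ = trimer
    site = SiteDefinition("s", [(1, "A"), (60, "A")], (-3, -2, -1, 1, 2))
    report = site_confidence(residue_confidence(model), model, site)
    assert report.window_sizes["A1"] == 3   # 1, 2, 3 exist
    assert report.window_sizes["A60"] == 4  # 57, 58, 59, 60 exist


def test_expected_code_mismatch_raises(trimer):
    model, _ = trimer
    site = SiteDefinition("s", [(10, "K")], ())
    with pytest.raises(ValueError, match="expected 'K'"):
        site_confidence(residue_confidence(model), model, site)


def test_all_key_residues_missing_raises(trimer):
    model, _ = trimer
    site = SiteDefinition("s", [(999, "A")], ())
    with pytest.raises(ValueError, match="no key residue"):
        site_confidence(residue_confidence(model), model, site)


def test_chain_average_of_identical_chains_equals_single_chain(trimer):
    model, _ = trimer
    site = SiteDefinition("s", [(30, "A")], (-1, 1))
    cmap = residue_confidence(model)
    averaged = site_confidence(cmap, model, site, chain_policy="average_all")
    single = site_confidence(cmap, model, site, chain_policy="single:A")
    assert averaged.per_residue[0][1] == pytest.approx(single.per_residue[0][1])
    assert averaged.n_chains_used == 3 and single.n_chains_used == 1


def test_invariance_to_chain_and_atom_ordering(trimer):
    model, _ = trimer
    site = SiteDefinition("s", [(20, "A"), (40, "A")], (-2, 1))
    baseline = site_confidence(residue_confidence(model), model, site)
    shuffled = StructureModel(
        id=model.id,
        chains=[
            Chain(
                id=c.id,
                residues=[
                    Residue(number=r.number, aa_code=r.aa_code, atoms=list(reversed(r.atoms)))
                    for r in c.residues
                ],
            )
            for c in reversed(model.chains)
        ],
    )
    report = site_confidence(residue_confidence(shuffled), shuffled, site)
    for (_, a), (_, b) in zip(baseline.per_residue, report.per_residue):
        assert a == pytest.approx(b, abs=1e-12)


def test_reported_means_bounded_by_contributing_values():
    spec = syn.FixtureSpec(
        seed=5, n_residues=40,
        confidence=syn.ConfidenceProfile(base=70.0, atom_noise_sigma=10.0),
    )
    model, truth = syn.make_trimer(spec)
    report = site_confidence(
        residue_confidence(model), model,
        SiteDefinition("s", [(20, "A")], (-3, -2, -1, 1, 2)),
    )
    window = [truth.residue_means[(c.id, n)] for c in model.chains for n in range(17, 23) if n != 20] + [
        truth.residue_means[(c.id, 20)] for c in model.chains
    ]
    assert min(window) <= report.per_residue[0][1] <= max(window)


@pytest.mark.parametrize(
    "values,expected",
    [
        (AF2_ALLOSTERIC, AF2_ALLOSTERIC_GLOBAL),
        (AF3_ORTHOSTERIC, AF3_ORTHOSTERIC_GLOBAL),
    ],
)
def test_global_average_of_published_site_means(values, expected):
    assert round(aggregate_global_mean(list(values.values())), 2) == expected


def test_global_average_singleton_and_empty():
    assert aggregate_global_mean([42.5]) == pytest.approx(42.5)
    with pytest.raises(ValueError):
        aggregate_global_mean([])


def _report_from(values: dict[int, float], code_by_number: dict[int, str]) -> SiteConfidenceReport:
    per_residue = [(f"{code_by_number[n]}{n}", v) for n, v in sorted(values.items())]
    return SiteConfidenceReport(
        site_name="s", per_residue=per_residue,
        global_average=float(np.mean(list(values.values()))), n_chains_used=3,
    )


def test_ranking_reproduces_extreme_residues():
    ortho_codes = {64: "K", 66: "K", 189: "T", 292: "N", 294: "R", 311: "K"}
    ranked = rank_site_residues(_report_from(AF2_ORTHOSTERIC, ortho_codes))
    assert ranked[0] == ("K311", 93.78)
    assert ranked[-1] == ("N292", 80.30)
    allo_codes = {88: "F", 95: "F", 103: "F", 105: "M", 293: "F", 312: "V"}
    ranked_af3 = rank_site_residues(_report_from(AF3_ALLOSTERIC, allo_codes))
    assert ranked_af3[-1] == ("F95", 74.12)
    assert ranked_af3[0] == ("V312", 88.47)


def test_ranking_tie_broken_by_residue_number():
    report = _report_from({10: 90.0, 5: 90.0, 20: 90.0}, {5: "A", 10: "A", 20: "A"})
    assert [label for label, _ in rank_site_residues(report)] == ["A5", "A10", "A20"]


def test_builtin_site_definitions_match_receptor_key_residues():
    site = orthosteric_site()
    assert [n for n, _ in site.key_residues] == [64, 66, 189, 292, 294, 311]
    assert site.neighbor_offsets == (-3, -2, -1, 1, 2)
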