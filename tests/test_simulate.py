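import json

import numpy as np
import pytest

from qreuse import (
    TARGET_PROGRAMS,
    detect_across_trial_reuse,
    extract_template,
    parse,
    program_distance,
    random_tree_edit,
    target_matching,
)
from qreuse.dataset import write_dataset
from qreuse.simulate import (
    AgentParams,
    StudyDesign,
    generate_dataset,
    instantiate_template,
)


class TestAgentParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho_reuse": 1.5},
            {"kappa_recombine": -0.1},
            {"beta_eig": -1.0},
            {"n_edits": 0},
            {"drop_rate": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AgentParams(**kwargs)


class TestGenerateDataset:
    def test_seed_determinism_is_byte_identical(self, tmp_path):
        design = StudyDesign.study1(n_participants=8, assignment_seed=4)
        paths = []
        for run in (0, 1):
            ds = generate_dataset(AgentParams(seed=9), design)
            p = tmp_path / f"run{run}.jsonl"
            write_dataset(ds, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_full_reuse_marks_every_eligible_trial(self):
        ds = generate_dataset(
            AgentParams(rho_reuse=1.0, beta_eig=0.0, seed=2),
            StudyDesign.study1(n_participants=10, assignment_seed=2),
        )
        flags = detect_across_trial_reuse(ds)
        assert flags and all(flags.values())

    def test_study_structure(self):
        ds = generate_dataset(AgentParams(seed=1), StudyDesign.study1(n_participants=12, assignment_seed=1))
        assert len(ds) == 48
        assert len(ds.participants) == 12
        for recs in ds.by_participant().values():
            assert [r.trial_index for r in recs] == [0, 1, 2, 3]
            assert len({r.array_id for r in recs}) == 4  # drawn without replacement

    def test_exposure_participants_reuse_the_target_first(self):
        """With rho=1 and an empty own history, the first reuse can only
        draw on the injected target question."""
        ds = generate_dataset(
            AgentParams(rho_reuse=1.0, seed=3), StudyDesign.study2(n_per_cell=4, assignment_seed=3)
        )
        for recs in ds.by_participant().values():
            first = recs[0]
            if first.exposure == "exposure":
                assert target_matching(first.program, first.target_id)

    def test_no_exposure_first_trial_cannot_reuse(self):
        ds = generate_dataset(
            AgentParams(rho_reuse=1.0, kappa_recombine=0.0, seed=3),
            StudyDesign.study2(n_per_cell=4, assignment_seed=3),
        )
        rate = np.mean(
            [
                target_matching(recs[0].program, recs[0].target_id)
                for recs in ds.by_participant().values()
                if recs[0].exposure == "no_exposure"
            ]
        )
        assert rate < 0.5  # only chance-level grammar collisions

    def test_drop_rate_removes_trials_but_keeps_order(self):
        ds = generate_dataset(
            AgentParams(drop_rate=0.3, seed=6), StudyDesign.study1(n_participants=20, assignment_seed=6)
        )
        assert len(ds) < 80
        for recs in ds.by_participant().values():
            idx = [r.trial_index for r in recs]
            assert idx == sorted(idx)

    def test_condition_labels_complete_in_study2(self):
        ds = generate_dataset(AgentParams(seed=8), StudyDesign.study2(n_per_cell=2, assignment_seed=8))
        assert ds.has_conditions
        assert len(ds) == 2 * 2 * 2 * 2 * 4  # exposure x quality x target x n, 4 trials

    def test_exposure_design_requires_known_target(self):
        with pytest.raises(ValueError):
            StudyDesign(
                arrays={},
                participant_specs=(
                    {"participant_id": "p", "array_ids": ["a"], "exposure": "exposure",
                     "target_id": "bogus"},
                ),
            )


class TestRandomTreeEdit:
    def test_output_always_type_checks_and_differs(self, rng):
        from qreuse.sampling import sample_program

        for _ in range(100):
            p = sample_program(rng=rng)
            try:
                e = random_tree_edit(p, rng)
            except ValueError:
                continue
            assert e.root_type in ("Boolean", "Number", "Shape")
            assert e.key != p.key

    def test_edit_kernel_is_local(self, rng):
        """An edited question stays closer (in TED) to its source than an
        independent grammar sample does."""
        from qreuse.sampling import sample_program

        edit_d, fresh_d = [], []
        for _ in range(150):
            p = sample_program(rng=rng)
            fresh_d.append(program_distance(p, sample_program(rng=rng)))
            try:
                edit_d.append(program_distance(p, random_tree_edit(p, rng)))
            except ValueError:
                pass
        assert np.mean(edit_d) < np.mean(fresh_d)

    def test_free_relabels_keep_distance_zero_but_change_program(self, rng):
        p = parse("(== (legs Red) 2)")
        seen_zero = False
        for _ in range(30):
            e = random_tree_edit(p, rng)
            if program_distance(p, e) == 0:
                seen_zero = True
                assert e.key != p.key
        assert seen_zero


class TestInstantiateTemplate:
    def test_instantiation_preserves_the_template(self, rng):
        from qreuse.sampling import sample_program

        for _ in range(50):
            t = extract_template(sample_program(rng=rng))
            inst = instantiate_template(t, rng)
            assert extract_template(inst) == t


class TestEigSensitivity:
    def test_high_beta_concentrates_reuse_on_informative_trials(self):
        """With strong EIG sensitivity, target reuse in the exposure cells
        tracks the target's informativeness gradient over trial types."""
        from scipy.stats import spearmanr

        from qreuse.information import expected_information_gain

        ds = generate_dataset(
            AgentParams(rho_reuse=0.6, beta_eig=5.0, seed=1),
            StudyDesign.study2(n_per_cell=40, assignment_seed=2),
        )
        rates, eigs = [], []
        for tt in ("best", "medium", "worst", "too_complex"):
            flags, gains = [], []
            for rec in ds.records:
                if rec.exposure == "exposure" and rec.trial_type == tt:
                    flags.append(target_matching(rec.program, rec.target_id))
                    gains.append(
                        expected_information_gain(
                            TARGET_PROGRAMS[rec.target_id], ds.array_for(rec)
                        )
                    )
            rates.append(np.mean(flags))
            eigs.append(np.mean(gains))
        rho, _ = spearmanr(rates, eigs)
        assert rho > 0
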