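"""ZOOPS EM motif discovery, architecture typing and subdomain mapping."""

import numpy as np
import pytest

from famforge.motifs import (
    MotifModel,
    _encode,
    _seed_pwm,
    _windows,
    classify_architecture,
    discover_motifs,
    map_subdomains,
    write_motifs,
    zoops_em,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
PLANTED = "GYWKATGKD"


def _planted_dataset(seed, n=20, length=60, motif=PLANTED):
    rng = np.random.default_rng(seed)
    seqs = {}
    offsets = {}
    for i in range(n):
        bg = "".join(np.array(list(AA))[rng.integers(0, 20, length)])
        off = int(rng.integers(0, length - len(motif)))
        seqs[f"p{i:02d}"] = bg[:off] + motif + bg[off + len(motif) :]
        offsets[f"p{i:02d}"] = off
    return seqs, offsets


def test_planted_nine_mer_recovered_exactly():
    seqs, offsets = _planted_dataset(3)
    (model,) = discover_motifs(seqs, n=1, wmin=6, wmax=20, seed=1)
    assert model.consensus == PLANTED
    assert model.width == len(PLANTED)
    found = dict(model.occurrences)
    assert len(found) == 20
    assert all(found[pid] == offsets[pid] for pid in offsets)


def test_em_objective_monotone_nondecreasing():
    seqs, _ = _planted_dataset(5)
    enc = [_encode(s) for s in seqs.values()]
    windows = [_windows(e, 9) for e in enc]
    bg = np.full(20, 0.05)
    res = zoops_em(windows, 9, bg, _seed_pwm(_encode(PLANTED), 9))
    assert (np.diff(res.trace) >= -1e-8).all()


def test_pwm_rows_normalized_after_em():
    seqs, _ = _planted_dataset(7)
    (model,) = discover_motifs(seqs, n=1, wmin=6, wmax=12, seed=0)
    assert np.allclose(model.pwm.sum(axis=1), 1.0, atol=1e-9)


def test_uniform_random_sequences_much_weaker_than_planted_signal():
    """On pure noise the best model is far less informative than on planted
    data: with only 20 sequences a regularised PWM always retains some
    apparent information, so the sound bound is comparative."""
    noise_ics, planted_ics = [], []
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        noise = {
            f"r{i}": "".join(np.array(list(AA))[rng.integers(0, 20, 60)])
            for i in range(20)
        }
        models = discover_motifs(noise, n=1, wmin=6, wmax=12, seed=seed)
        noise_ics.append(models[0].information_content if models else 0.0)
        planted, _ = _planted_dataset(seed)
        planted_models = discover_motifs(planted, n=1, wmin=6, wmax=12, seed=seed)
        planted_ics.append(planted_models[0].information_content)
    assert float(np.mean(noise_ics)) < 0.5 * float(np.mean(planted_ics))


def test_two_disjoint_motifs_both_recovered():
    rng = np.random.default_rng(11)
    second = "LMHPWQRNV"
    seqs = {}
    for i in range(20):
        bg = "".join(np.array(list(AA))[rng.integers(0, 20, 70)])
        seqs[f"q{i:02d}"] = bg[:5] + PLANTED + bg[5:40] + second + bg[40:]
    models = discover_motifs(seqs, n=2, wmin=6, wmax=20, seed=2)
    assert {m.consensus for m in models} == {PLANTED, second}
    assert all(len(m.occurrences) == 20 for m in models)


def test_discovery_deterministic_for_fixed_seed():
    seqs, _ = _planted_dataset(9)
    m1 = discover_motifs(seqs, n=2, wmin=6, wmax=15, seed=4)
    m2 = discover_motifs(seqs, n=2, wmin=6, wmax=15, seed=4)
    assert [m.consensus for m in m1] == [m.consensus for m in m2]
    assert [m.occurrences for m in m1] == [m.occurrences for m in m2]


def test_zero_motifs_requested():
    seqs, _ = _planted_dataset(1)
    assert discover_motifs(seqs, n=0, wmin=6, wmax=9, seed=0) == []


def test_too_few_proteins_rejected():
    with pytest.raises(ValueError):
        discover_motifs({"a": "MKVT" * 10}, n=1, wmin=6, wmax=9, seed=0)


# ---------------------------------------------------------------------------
# architecture typing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "present,expected",
    [
        ({1, 2, 3, 4, 5, 6, 7, 8}, "A"),
        ({1, 2, 3, 5, 6, 7, 8}, "B"),
        ({1, 6, 7, 8, 9}, "C"),
        ({5, 6, 7, 8, 10}, "D"),
        ({1, 2, 3, 4, 5, 6, 7, 8, 9}, "C"),  # precedence: 9 beats the A set
        ({1, 2, 3, 4, 5, 6, 7, 8, 10}, "D"),
        ({5, 6, 7, 8}, "other"),
        (set(), "other"),
    ],
)
def test_architecture_classification(present, expected):
    assert classify_architecture("p", set(present)).structure == expected


def test_architecture_pure_function():
    a = classify_architecture("p", {8, 1, 3, 2, 7, 5, 6, 4})
    b = classify_architecture("p", {1, 2, 3, 4, 5, 6, 7, 8})
    assert a.structure == b.structure == "A"
    assert a.present_motifs == b.present_motifs


def test_architecture_rejects_bad_index():
    with pytest.raises(ValueError):
        classify_architecture("p", {0, 1})


# ---------------------------------------------------------------------------
# subdomain mapping
# ---------------------------------------------------------------------------

def _model(index, consensus, offsets):
    w = len(consensus)
    pwm = np.full((w, 20), 0.01 / 19)
    for i, c in enumerate(consensus):
        pwm[i, AA.index(c)] = 0.99
    pwm = pwm / pwm.sum(axis=1, keepdims=True)
    occ = [(f"p{i}", off) for i, off in enumerate(offsets)]
    return MotifModel(index, w, pwm, np.full(20, 0.05), occ)


def test_anchor_consensi_map_to_expected_motifs():
    consensi = {
        1: ("SDEELVVHY", [2, 3]),
        2: ("GEREWYFFS", [18, 19]),
        3: ("PWDLPSKAK", [34, 35]),
        4: ("NGSRPNRAT", [48, 49]),
        5: ("GYWKATGADQI", [60, 61]),   # matches G-Y-W-K-A/T-T-G-x-D-x{1,2}-I/V
        6: ("GEKKALVFY", [80, 81]),     # matches G-x-K-K-x-L-V-F-Y
        7: ("TRWIMHEY", [95, 96]),      # matches T-x-W-x-M-H-E-Y
        8: ("LDDWVLCRI", [110, 111]),
        9: ("HQNKFPNQV", [120, 121]),
        10: ("QTPSSMMNF", [150, 151]),
    }
    models = [_model(i + 1, cons, offs) for i, (cons, offs) in enumerate(
        consensi[k] for k in sorted(consensi)
    )]
    sd = map_subdomains(models)
    assert sd.consensus[5] == "GYWKATGADQI"
    assert sd.consensus[6] == "GEKKALVFY"
    assert sd.consensus[7] == "TRWIMHEY"
    assert sd.mapping[5] == "C" and sd.mapping[6] == "D" and sd.mapping[7] == "D"
    # remaining models numbered by mean occurrence offset
    assert sd.consensus[1] == "SDEELVVHY" and sd.mapping[1] == "A"
    assert sd.consensus[2] == "GEREWYFFS" and sd.mapping[2] == "B"
    assert sd.consensus[8] == "LDDWVLCRI" and sd.mapping[8] == "E"
    assert sd.mapping[10] == "TRR"


def test_map_subdomains_requires_ten_models():
    with pytest.raises(ValueError):
        map_subdomains([_model(1, "SDEELVVHY", [0])])


def test_motif_file_written(tmp_path):
    m = _model(1, "GYWKATGKD", [0, 5])
    write_motifs([m], tmp_path / "m.txt")
    text = (tmp_path / "m.txt").read_text()
    assert "GYWKATGKD" in text and "w= 9" in text
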