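import pytest

from sstkit import (
    CurationConfig,
    CurationFlag,
    SequenceRecord,
    assign_flags,
    derive_mature,
    filter_canonical,
    flag_matures,
)

CANONICAL_MATURE = (
    "R" + "AAAAA" + "YW" + "AAA" + "M" + "AAA" + "PAP" + "AA" + "I" + "AA" + "LL"
    + "A" * 10 + "F" + "AAA" + "F" + "AAAAA" + "II" + "YH" + "GGGGGG"
)  # 55 aa, both conserved regions


def _record(mature=CANONICAL_MATURE, sp="M" + "A" * 24, sp_annotated=True, id="r1"):
    return SequenceRecord(
        id=id, residues=sp + mature, sp_length=len(sp) if sp_annotated else None
    )


def test_derive_mature_strips_signal_peptide():
    rec = SequenceRecord(id="r", residues="M" + "L" * 24 + "R" * 57, sp_length=25)
    m = derive_mature(rec)
    assert m.length_aa == 57
    assert m.residues == "R" * 57
    assert CurationFlag.NO_SP not in m.flags


def test_derive_mature_without_sp_keeps_full_sequence():
    rec = SequenceRecord(id="r", residues="MKKRYW")
    m = derive_mature(rec)
    assert m.residues == rec.residues
    assert CurationFlag.NO_SP in m.flags


def test_derive_mature_rejects_sp_covering_sequence():
    with pytest.raises(Exception):
        derive_mature(SequenceRecord(id="r", residues="MKKRYW", sp_length=6))


def test_canonical_mature_gets_no_flags():
    m = derive_mature(_record())
    assert assign_flags(m) == frozenset()


def test_truncated_flag_below_50_aa():
    m = derive_mature(_record(mature=CANONICAL_MATURE[:40]))
    assert CurationFlag.TRUNCATED_CTERM in assign_flags(m)


def test_truncated_flag_when_region2_missing():
    # long enough, region 1 intact, second conserved block removed
    mature = CANONICAL_MATURE[:30] + "G" * 30
    m = derive_mature(_record(mature=mature))
    assert CurationFlag.TRUNCATED_CTERM in assign_flags(m)


def test_oversize_flag_above_90_aa():
    m = derive_mature(_record(mature=CANONICAL_MATURE + "G" * 60))
    assert m.length_aa == 115
    assert CurationFlag.OVERSIZE in assign_flags(m)


def test_noncanonical_start_flag():
    m = derive_mature(_record(mature="Q" + CANONICAL_MATURE[1:]))
    flags = assign_flags(m)
    assert CurationFlag.NONCANONICAL_START in flags
    assert CurationFlag.EXTRA_NTERM not in flags


def test_extra_nterm_flag_and_trim():
    m = derive_mature(_record(mature="GGG" + CANONICAL_MATURE))
    flags = assign_flags(m)
    assert {CurationFlag.NONCANONICAL_START, CurationFlag.EXTRA_NTERM} <= flags
    kept, removed = filter_canonical([m.with_flags(flags)])
    assert len(kept) == 1
    assert kept[0].residues == CANONICAL_MATURE
    assert kept[0].flags == frozenset()
    assert removed[0][1] == "*4 (trimmed form retained)"


def test_outlier_exclusion_is_config_driven():
    cfg = CurationConfig(outlier_ids=frozenset({"r1"}))
    m = derive_mature(_record())
    assert CurationFlag.OUTLIER in assign_flags(m, cfg)


def test_flag_assignment_idempotent():
    m = derive_mature(_record(mature="GGG" + CANONICAL_MATURE))
    once = assign_flags(m)
    assert assign_flags(m.with_flags(once)) == once


def test_filter_removes_no_sp_entries():
    records = [_record(id=f"c{i}") for i in range(3)] + [_record(id="nosp", sp_annotated=False)]
    kept, removed = filter_canonical(flag_matures(records))
    assert len(kept) == 3
    assert len(removed) == 1
    assert removed[0][1] == "*2"


def test_filter_all_canonical_removes_nothing():
    kept, removed = filter_canonical(flag_matures([_record(id=f"c{i}") for i in range(4)]))
    assert len(kept) == 4 and removed == []


def test_filter_accounts_for_every_input(flagged_bundle):
    """Every input id ends up in kept or removed; trimmed forms replace
    their originals in kept and are traceable via parent_id."""
    matures = flag_matures(flagged_bundle.records)
    kept, removed = filter_canonical(matures)
    input_ids = {m.id for m in matures}
    removed_ids = {m.id for m, _ in removed}
    kept_original = {m.id for m in kept if not m.id.endswith("|trimmed")}
    assert kept_original | removed_ids == input_ids
    assert not (kept_original & removed_ids)
    trimmed = [m for m in kept if m.id.endswith("|trimmed")]
    assert all(m.id[: -len("|trimmed")] in removed_ids for m in trimmed)


def test_planted_flags_recovered_exactly(flagged_bundle):
    """Precision and recall 1.0 for every flag class at zero noise."""
    matures = flag_matures(flagged_bundle.records)
    truth = flagged_bundle.truth_by_id
    for flag in CurationFlag:
        if flag == CurationFlag.OUTLIER:
            continue
        predicted = {m.id for m in matures if flag in m.flags}
        planted = {t.id for t in truth.values() if flag in t.planted_flags}
        assert predicted == planted, flag
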