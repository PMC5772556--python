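"""Parsing, curation, coordinate conventions, extension and splitting."""

import numpy as np
import pytest

from predcrp import BindingSite, SiteDataset, curate, extend_site, parse_site_table, split_dataset
from predcrp.sites import (
    DictFlankSource,
    RejectReport,
    _relative_interval,
    write_site_table,
)

from conftest import make_site_table, site_row


def test_parse_populates_all_fields(tmp_path):
    rows = [site_row(i, left=900 + i) for i in range(6)]
    ds = parse_site_table(make_site_table(tmp_path / "t.tsv", rows))
    assert len(ds) == 6
    s = ds.sites[0]
    assert (s.tf_name, s.evidence, s.role) == ("CRP", "strong", "activator")
    assert s.length == 22 == len(s.core_seq)


def test_minus_strand_reflection(tmp_path):
    # site 40 nt 5' of the TSS on the genome, minus strand: on the
    # TSS-relative axis it must land on the negative (upstream) side
    row = site_row(0, strand="-", tss=1000)
    row["left"], row["right"] = 1019, 1040  # genomic 5' of a minus-strand TSS
    ds = parse_site_table(make_site_table(tmp_path / "t.tsv", [row]))
    s = ds.sites[0]
    assert (s.left, s.right) == (-40, -19)


def test_strand_reflection_is_involution():
    for left, right, tss in [(900, 921, 1000), (1010, 1031, 1000)]:
        rl, rr = _relative_interval(left, right, tss, "-")
        # reflecting the relative interval again restores the genomic one
        assert (tss - rr, tss - rl) == (left, right)


def test_parse_empty_table(tmp_path):
    ds = parse_site_table(make_site_table(tmp_path / "t.tsv", []))
    assert len(ds) == 0


def test_parse_rejects_malformed_rows(tmp_path):
    rows = [site_row(0), site_row(1)]
    rows[1]["left"] = "not-a-number"
    report = RejectReport()
    ds = parse_site_table(make_site_table(tmp_path / "t.tsv", rows), reject_report=report)
    assert len(ds) == 1
    assert len(report) == 1 and "coordinate" in report.rows[0][1]


def test_parse_missing_column_is_config_error(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("site_id\tleft\n1\t5\n")
    with pytest.raises(Exception, match="mandatory"):
        parse_site_table(path)


def test_curate_filters_in_order(tmp_path):
    rows = [
        site_row(0, tf="FNR"),                          # wrong TF
        site_row(1, evidence="weak"),                   # weak evidence
        site_row(2, left=940),                          # duplicate pair (kept)
        site_row(3, left=940),                          # duplicate pair (dropped)
        site_row(4, left=950, seq="A" * 21),            # wrong length
        site_row(5, left=960),                          # clean
    ]
    ds = parse_site_table(make_site_table(tmp_path / "t.tsv", rows))
    curated = curate(ds, tf="CRP", evidence="strong")
    assert [s.site_id for s in curated] == ["s2", "s5"]


def test_curate_is_idempotent(tmp_path):
    rows = [site_row(i, left=900 + 30 * i) for i in range(5)]
    ds = parse_site_table(make_site_table(tmp_path / "t.tsv", rows))
    once = curate(ds)
    twice = curate(once)
    assert [s.site_id for s in once] == [s.site_id for s in twice]


def test_curate_identity_on_clean_input(tmp_path):
    rows = [site_row(i, left=900 + 30 * i) for i in range(4)]
    ds = parse_site_table(make_site_table(tmp_path / "t.tsv", rows))
    assert [s.site_id for s in curate(ds)] == [s.site_id for s in ds]


def _site(seq="ACGT" * 5 + "AC", left=-50):
    return BindingSite(
        site_id="x", tf_name="CRP", gene="g", core_seq=seq,
        left=left, right=left + len(seq) - 1, strand="+",
        evidence="strong", role="activator",
    )


class TestExtendSite:
    def test_k10_gives_42nt(self):
        src = DictFlankSource({"x": ("G" * 10, "C" * 10)})
        ext = extend_site(_site(), src, k=10)
        assert len(ext.extended_seq) == 42
        assert ext.extended_seq[10:32] == ext.core_seq
        assert (ext.left, ext.right) == (-50, -29)

    def test_k0_identity(self):
        ext = extend_site(_site(), DictFlankSource({}), k=0)
        assert ext.extended_seq == ext.core_seq

    def test_short_flank_is_n_padded(self):
        src = DictFlankSource({"x": ("GG", "C")})
        with pytest.warns(UserWarning, match="N-padding"):
            ext = extend_site(_site(), src, k=10)
        assert len(ext.extended_seq) == 42
        assert ext.extended_seq.startswith("N" * 8 + "GG")
        assert ext.extended_seq.endswith("C" + "N" * 9)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            extend_site(_site(), DictFlankSource({}), k=-1)


class TestSplit:
    def _dataset(self, n_act=133, n_rep=36):
        sites = [_site() for _ in range(n_act + n_rep)]
        out = []
        for i, s in enumerate(sites):
            s = BindingSite(**{**s.__dict__, "site_id": f"s{i:03d}",
                               "role": "repressor" if i < n_rep else "activator"})
            out.append(s)
        return SiteDataset(out)

    def test_reproduces_published_partition_sizes(self):
        train, test = split_dataset(self._dataset(), ratio=(2, 1), seed=0)
        assert (len(train), len(test)) == (113, 56)
        assert sum(s.role == "repressor" for s in train) == 24
        assert sum(s.role == "activator" for s in train) == 89
        assert sum(s.role == "repressor" for s in test) == 12
        assert sum(s.role == "activator" for s in test) == 44

    def test_split_is_a_partition(self):
        ds = self._dataset(20, 10)
        train, test = split_dataset(ds, seed=4)
        ids = {s.site_id for s in ds}
        tr = {s.site_id for s in train}
        te = {s.site_id for s in test}
        assert tr | te == ids and not (tr & te)

    def test_deterministic_under_seed(self):
        ds = self._dataset(30, 12)
        a = split_dataset(ds, seed=7)
        b = split_dataset(ds, seed=7)
        assert [s.site_id for s in a[0]] == [s.site_id for s in b[0]]

    def test_ratio_one_zero_puts_all_in_train(self):
        ds = self._dataset(9, 3)
        train, test = split_dataset(ds, ratio=(1, 0), seed=0)
        assert len(train) == 12 and len(test) == 0


def test_site_table_roundtrip(tmp_path, synthetic_clean):
    dataset, _ = synthetic_clean
    path = tmp_path / "sites.tsv"
    write_site_table(dataset, path)
    back = parse_site_table(path)
    assert len(back) == len(dataset)
    for a, b in zip(dataset, back):
        assert (a.site_id, a.core_seq, a.left, a.right, a.role) == (
            b.site_id, b.core_seq, b.left, b.right, b.role
        )
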