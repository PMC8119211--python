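import numpy as np
import pytest

from cffrag.io import FragmentSet, SizeProfile, build_profile


@pytest.fixture
def two_length_profile() -> SizeProfile:
    """f(166) = 0.75, f(145) = 0.25 on [30, 440]."""
    fs = FragmentSet(counts={166: 3, 145: 1})
    return build_profile(fs, (30, 440))


@pytest.fixture
def uniform_profile() -> SizeProfile:
    """One fragment at each length of [100, 199]."""
    fs = FragmentSet(counts={l: 1 for l in range(100, 200)})
    return build_profile(fs, (100, 199))


def profile_from_freqs(freqs: dict[int, float], support=None, assay="RAW",
                       n=10_000) -> SizeProfile:
    """Build a SizeProfile directly from a frequency mapping."""
    lo = min(freqs) if support is None else support[0]
    hi = max(freqs) if support is None else support[1]
    dense = np.zeros(hi - lo + 1)
    for l, f in freqs.items():
        dense[l - lo] = f
    dense = dense / dense.sum()
    return SizeProfile(assay=assay, support=(lo, hi), freqs=dense, n_fragments=n)


@pytest.fixture
def bam_file(tmp_path):
    """Tiny coordinate-sorted, indexed BAM with three proper pairs and one
    duplicate-flagged pair; TLENs 166, 145, 320 (plus the duplicate at 200)."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"LN": 100000, "SN": "chr1"}]}
    path = tmp_path / "frags.bam"

    def pair(name, start, tlen, flag_extra=0):
        a = pysam.AlignedSegment()
        a.query_name = name
        a.query_sequence = "A" * 50
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 60
        a.cigar = [(0, 50)]
        a.next_reference_id = 0
        a.next_reference_start = start + tlen - 50
        a.template_length = tlen
        a.flag = 0x1 | 0x2 | 0x40 | 0x20 | flag_extra  # paired, proper, read1, mate rev
        b = pysam.AlignedSegment()
        b.query_name = name
        b.query_sequence = "A" * 50
        b.reference_id = 0
        b.reference_start = start + tlen - 50
        b.mapping_quality = 60
        b.cigar = [(0, 50)]
        b.next_reference_id = 0
        b.next_reference_start = start
        b.template_length = -tlen
        b.flag = 0x1 | 0x2 | 0x80 | 0x10 | flag_extra
        return [a, b]

    reads = []
    reads += pair("p166", 100, 166)
    reads += pair("p145", 1000, 145)
    reads += pair("p320", 2000, 320)
    reads += pair("pdup", 3000, 200, flag_extra=0x400)  # duplicate
    reads.sort(key=lambda r: r.reference_start)
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for r in reads:
            out.write(r)
    pysam.index(str(path))
    return path
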