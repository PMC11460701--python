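import warnings

import pytest

from flexiscan import annotations, detect


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def make_catalog(intervals, chrom="chr1", strand="+", short_threshold=300):
    """Catalog from a list of (start, end) or (start, end, strand) tuples."""
    records = []
    for iv in intervals:
        s, e = iv[0], iv[1]
        st = iv[2] if len(iv) > 2 else strand
        records.append(
            annotations.IntronRecord(
                chrom=chrom, start=s, end=e, strand=st, gene_id="G", gene_name="G"
            )
        )
    return annotations.IntronCatalog(records, short_threshold=short_threshold)


def make_fragment(start, end, chrom="chr1", strand="+", continuous=True, mates=None):
    return detect.AlignmentFragment(
        chrom=chrom,
        frag_start=start,
        frag_end=end,
        strand=strand,
        is_continuous=continuous,
        mate_spans=mates or ((start, end), (start, end)),
    )
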