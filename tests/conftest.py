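"""Shared fixtures: toy alignments and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from permod import GeneratorConfig, simulate_feature_dataset, simulate_modprob_dataset

REF_NAME = "ref1"
REF_SEQ = "CCAACCTAGCAACTTAACCGGAACCATACCAACC"  # 34 nt, A-rich


def make_sam(path, reads):
    """Write a tiny SAM file.

    ``reads`` is a list of dicts with query_name, seq, ref_start, and
    optionally is_reverse, mm (MM tag string), ml (list of ints).
    Alignments are full-length matches (cigar = len(seq)M).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": REF_NAME, "LN": 1000}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for spec in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = spec["query_name"]
            a.query_sequence = spec["seq"]
            a.reference_id = 0
            a.reference_start = spec["ref_start"]
            a.mapping_quality = 60
            a.cigarstring = f"{len(spec['seq'])}M"
            a.flag = 16 if spec.get("is_reverse") else 0
            if spec.get("unmapped"):
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.cigarstring = None
            if "mm" in spec:
                a.set_tag("MM", spec["mm"])
            if "ml" in spec:
                import array
                a.set_tag("ML", array.array("B", spec["ml"]))
            out.write(a)
    return str(path)


@pytest.fixture
def sam_factory(tmp_path):
    def _factory(reads, name="toy.sam"):
        return make_sam(tmp_path / name, reads)
    return _factory


@pytest.fixture(scope="session")
def strong_effect_dataset():
    """Paired feature dataset with strong effects at 50% stoichiometry."""
    cfg = GeneratorConfig(seed=11, n_reads_per_sample=200,
                          n_affected_kmers=3, n_unaffected_kmers=3,
                          stoichiometry=0.5, residual=0.0)
    return simulate_feature_dataset(cfg)


def calls_frame(rows):
    """Build a per-read call table from (read_id, ref, pos, strand, p) rows."""
    return pd.DataFrame(
        [{"read_id": r, "ref_id": c, "pos": p, "strand": s,
          "base": "A", "mod_prob": mp} for r, c, p, s, mp in rows]
    )


def pileup_calls(chrom, pos, probs, strand="+"):
    """One site covered by len(probs) reads with the given modProbs."""
    return pd.DataFrame({
        "read_id": [f"r{i}" for i in range(len(probs))],
        "ref_id": chrom, "pos": pos, "strand": strand,
        "base": "A", "mod_prob": np.asarray(probs, dtype=float),
    })


@pytest.fixture(scope="session")
def pools():
    """Fully modified and fully unmodified read pools (4,500 reads each)."""
    mod, _ = simulate_modprob_dataset(GeneratorConfig(
        seed=8, n_reads=4500, n_sites=2, stoichiometry=1.0, residual=0.0,
        read_prefix="mod"))
    unmod, _ = simulate_modprob_dataset(GeneratorConfig(
        seed=9, n_reads=4500, n_sites=2, stoichiometry=0.0, residual=0.0,
        read_prefix="unmod"))
    return mod, unmod
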