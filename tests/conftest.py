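import numpy as np
import pandas as pd
import pytest

from poolcoev.panel import ReferencePanel


@pytest.fixture
def toy_panel() -> ReferencePanel:
    """Five strains, one 10-column contig, hand-designed columns.

    Column-by-column (0-based):
      0: AAAAA  monomorphic
      1: AAAAG  diagnostic for S5 (allele G)
      2: AAAGG  two strains substituted -> not diagnostic
      3: ACGTA  four alleles -> not diagnostic
      4: AAGAA  diagnostic for S3 (allele G)
      5: A-AAA  gap -> not diagnostic
      6: TTTTT  monomorphic
      7: CAAAA  diagnostic for S1 (allele C)
      8: AANAA  N -> not diagnostic
      9: GGGGC  diagnostic for S5 (allele C)
    """
    cols = [
        "AAAAA", "AAAAG", "AAAGG", "ACGTA", "AAGAA",
        "A-AAA", "TTTTT", "CAAAA", "AANAA", "GGGGC",
    ]
    seqs = ["".join(col[i] for col in cols) for i in range(5)]
    contig_table = pd.DataFrame(
        {"contig": ["c1"], "start": [0], "end": [10], "role": ["chromosomal"]}
    )
    return ReferencePanel(
        strain_ids=["S1", "S2", "S3", "S4", "S5"],
        aligned_sequences=seqs,
        contig_table=contig_table,
        focal_strain="S1",
    )


@pytest.fixture
def variant_fixture() -> pd.DataFrame:
    """12 hand-built variant records exercising every filter.

    Expected under apply_all (defaults): the coverage-quantile step passes
    through (fewer than 50 records); strand bias drops v2 and v10; indel
    collision drops SNPs v4 and v11; MAF drops v5 (5% not > 5%) and v9
    (alt 0). Survivors: v1, v3, v6, v7, v8, v12.
    """
    rows = [
        # id, pos, type, depth, alt, af, ar, rf, rr
        ("v1", 100, "SNP", 100, 40, 20, 20, 30, 30),
        ("v2", 200, "SNP", 100, 20, 20, 0, 40, 40),
        ("v3", 300, "indel", 100, 30, 15, 15, 35, 35),
        ("v4", 300, "SNP", 100, 30, 15, 15, 35, 35),
        ("v5", 400, "SNP", 100, 5, 3, 2, 47, 48),
        ("v6", 500, "SNP", 100, 6, 3, 3, 47, 47),
        ("v7", 600, "indel", 80, 8, 4, 4, 36, 36),
        ("v8", 700, "SNP", 120, 60, 30, 30, 30, 30),
        ("v9", 800, "SNP", 100, 0, 0, 0, 50, 50),
        ("v10", 900, "SNP", 100, 50, 50, 0, 0, 50),
        ("v11", 1000, "SNP", 100, 30, 15, 15, 35, 35),
        ("v12", 1000, "indel", 100, 30, 15, 15, 35, 35),
    ]
    return pd.DataFrame(
        [
            {
                "id": rid,
                "sample": "P1",
                "contig": "c1",
                "position": pos,
                "type": typ,
                "ref": "A",
                "alt": "G" if typ == "SNP" else "GA",
                "depth": dp,
                "alt_count": ac,
                "alt_fwd": af,
                "alt_rev": ar,
                "ref_fwd": rf,
                "ref_rev": rr,
            }
            for rid, pos, typ, dp, ac, af, ar, rf, rr in rows
        ]
    )


@pytest.fixture
def coverage_matrix_factory():
    """Build a CoverageMatrix from a depth array (positions x samples)."""
    from poolcoev.cnv import CoverageMatrix

    def make(depths: np.ndarray, contig: str = "c1", role: str = "chromosomal"):
        depths = np.asarray(depths)
        idx = pd.MultiIndex.from_product(
            [[contig], range(depths.shape[0])], names=["contig", "position"]
        )
        cols = [f"s{j}" for j in range(depths.shape[1])]
        return CoverageMatrix(
            depths=pd.DataFrame(depths, index=idx, columns=cols),
            roles={contig: role},
        )

    return make
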