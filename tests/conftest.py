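import numpy as np
import pytest

from rarecase import (
    Annotation,
    GenotypeMatrix,
    PlantedVariantSpec,
    SampleRecord,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small structured cohort with two planted case-only variants."""
    cfg = SimulationConfig(
        n_cases=150,
        n_controls=150,
        n_background_snps=400,
        n_subpops=2,
        subpop_weights=(0.7, 0.3),
        planted=[
            PlantedVariantSpec(gene="NOTCH3", impact="MODERATE",
                               consequence="missense_variant", case_carriers=10),
            PlantedVariantSpec(gene="ABCA7", impact="HIGH",
                               consequence="stop_gained", case_carriers=7),
        ],
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def toy_cohort():
    """Hand-built 6-sample, 4-variant cohort with known counts."""
    #            v1 v2 v3 v4
    dosage = np.array(
        [
            [1, 0, 2, -1],   # case
            [1, 0, 0, -1],   # case
            [0, 1, 0, -1],   # case
            [0, 0, 0, -1],   # control
            [0, 1, 0, -1],   # control
            [-1, 0, 0, -1],  # control
        ],
        dtype=np.int8,
    )
    ids = [f"S{i}" for i in range(1, 7)]
    gm = GenotypeMatrix(ids, ["1:100:A:T", "1:200:C:G", "1:300:G:A", "1:400:T:C"], dosage)
    samples = [
        SampleRecord(ids[i], "case" if i < 3 else "control") for i in range(6)
    ]
    anns = [
        Annotation("1:100:A:T", "GENE1", "missense_variant", "MODERATE", {"nfe": 0.0001}),
        Annotation("1:200:C:G", "GENE2", "stop_gained", "HIGH", {"nfe": 0.0005}),
        Annotation("1:300:G:A", "GENE1", "synonymous_variant", "LOW", {"nfe": 0.02}),
        Annotation("1:400:T:C", "GENE3", "missense_variant", "MODERATE", {}),
    ]
    return gm, samples, anns


def write_minimal_vcf(path, body_lines, samples=("S1", "S2")):
    """Helper: write a VCF with the standard minimal header plus body lines."""
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + "".join(line.rstrip("\n") + "\n" for line in body_lines))
    return path
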