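import textwrap

import pytest

from panelyield import synthetic_cohort as sc
from panelyield.pipeline import RunConfig, run_full


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A generated ~500-sample cohort with clean (uncorrupted) genotypes."""
    out = tmp_path_factory.mktemp("cohort_small")
    cfg = sc.GeneratorConfig(seed=42, strata=sc.default_strata(170))
    return sc.generate(cfg, out)


@pytest.fixture(scope="session")
def small_run(small_cohort, tmp_path_factory):
    """Full pipeline output on the small cohort."""
    out = tmp_path_factory.mktemp("run_small")
    cfg = run_config_for(small_cohort, out)
    return run_full(cfg)


def run_config_for(gen: sc.GeneratedCohort, out_dir, **kw) -> RunConfig:
    return RunConfig(
        vcf=str(gen.vcf_path),
        phenotypes=str(gen.phenotype_path),
        annotations=str(gen.annotation_path),
        panel=str(gen.panel_path),
        lcr=str(gen.lcr_path),
        known_variants=str(gen.known_path),
        out_dir=str(out_dir),
        **kw,
    )


TOY_VCF = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=250000000>
    ##FILTER=<ID=VQSRTrancheSNP99.90to100.00,Description="fail">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
    chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT:DP:GQ:AD\t0/1:40:99:20,20\t0/0:35:99:35,0\t1/1:30:99:0,30
    chr1\t200\t.\tG\tC,T\t50\tPASS\t.\tGT:DP:GQ:AD\t0/1:40:99:22,18,0\t0/2:42:99:20,0,22\t0/0:33:99:33,0,0
    """)


TOY_PHENOTYPES = textwrap.dedent("""\
    sample_id\tage\tgrade\tsex\tsphere_r\tcyl_r\tva_r\tsphere_l\tcyl_l\tva_l
    S1\t10\tprimary\tmale\t-6.0\t-1.0\t0.5\t-6.5\t-0.5\t0.5
    S2\t13\tjunior\tfemale\t-8.0\t-1.0\t0.6\t-8.5\t-0.5\t0.6
    S3\t16\tsenior\tmale\t-10.0\t-1.0\t0.4\t-11.0\t0.0\t0.4
    """)


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def toy_phenotypes(tmp_path):
    path = tmp_path / "pheno.tsv"
    path.write_text(TOY_PHENOTYPES)
    return path
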