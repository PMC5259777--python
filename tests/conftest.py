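import pytest

from snpclust.catalog_io import Catalog, SnpAssociation
from snpclust.synthetic_data import table1_fixture

ANCHOR = "height"
PARTNERS = {"breast_cancer", "colorectal_cancer"}


@pytest.fixture(scope="session")
def fx():
    """The packaged transcription of the published prioritised-cluster table."""
    return table1_fixture()


def make_snp(rsid="rs1", chrom="1", pos=100, phenotype="height",
             p=1e-8, maf=0.2, **kw) -> SnpAssociation:
    return SnpAssociation(rsid=rsid, chrom=chrom, pos=pos, phenotype=phenotype,
                          p_value=p, maf=maf, **kw)


def make_catalog(*records) -> Catalog:
    return Catalog(records=list(records))
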