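import pytest

from katalogkit import HitRecord

OBO_TEXT = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: mid process
namespace: biological_process
is_a: GO:0000001 ! root process
subset: goslim_test

[Term]
id: GO:0000003
name: leaf process
namespace: biological_process
is_a: GO:0000002 ! mid process

[Term]
id: GO:0000010
name: left slim
namespace: molecular_function
subset: goslim_test

[Term]
id: GO:0000011
name: right slim
namespace: molecular_function
subset: goslim_test

[Term]
id: GO:0000012
name: diamond leaf
namespace: molecular_function
is_a: GO:0000010 ! left slim
is_a: GO:0000011 ! right slim

[Term]
id: GO:0000099
name: gone
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture
def obo_path(tmp_path):
    path = tmp_path / "mini.obo"
    path.write_text(OBO_TEXT)
    return path


def mk_hit(
    query_id="c1",
    subject_id="p1",
    identity=90.0,
    qstart=1,
    qend=300,
    sstart=1,
    send=100,
    e_value=1e-50,
    bit_score=200.0,
    subject_length=100,
    taxon="fish",
    database_tag="db1",
    description="",
    species=None,
    gene_id=None,
    alignment_length=None,
):
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        database_tag=database_tag,
        percent_identity=identity,
        alignment_length=alignment_length if alignment_length is not None else abs(send - sstart) + 1,
        query_start=qstart,
        query_end=qend,
        subject_start=sstart,
        subject_end=send,
        e_value=e_value,
        bit_score=bit_score,
        subject_length=subject_length,
        subject_species=species,
        subject_gene_id=gene_id,
        subject_taxon_group=taxon,
        description=description,
    )
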