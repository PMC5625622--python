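import json
import threading
from http.server import BaseHTTPRequestHandler, HTTPServer
from urllib.parse import parse_qs, urlparse

import pytest

from rdfacets import (QueryEngine, Store, build_index, convert_table,
                      generate_integration_table, hbv_structure,
                      parse_structure_config)

FIG1_CONFIG = """\
collections:
  - name: NCBI
databases:
  - name: dbSNP
    namespace: https://example.org/dbsnp/
    parent: NCBI
    columns:
      - column: SNP_Name
        display_name: Name of the SNP
        entity_type: snp
  - name: refSeq
    namespace: https://example.org/refseq/
    parent: NCBI
    columns: []
  - name: PubMed
    namespace: https://example.org/pubmed/
    columns: []
"""

# A SNP-style table exercising dependency prefixing, hidden columns,
# non-indexed columns and entity typing.
SNP_CONFIG = """\
databases:
  - name: snps
    namespace: https://example.org/snps/
    columns:
      - column: SNP_Name
        display_name: Name of the SNP
        display_order: 0
        entity_type: snp
      - column: gene
        display_name: Gene
        display_order: 1
        entity_type: gene
      - column: chromosome
        display_name: Chromosome
        display_order: 2
      - column: coordinate
        display_name: Coordinate
        display_order: 3
        datatype: integer
        depends_on: chromosome
        indexed: false
      - column: p_value
        display_name: P value
        display_order: 4
        datatype: decimal
        indexed: false
      - column: bin
        display_name: Bin
        display_order: 5
        hidden: true
"""

SNP_ROWS = [
    {"SNP_Name": "rs100", "gene": "TERT", "chromosome": "chr5",
     "coordinate": "1253", "p_value": "0.01", "bin": "b1"},
    {"SNP_Name": "rs101", "gene": "TERT", "chromosome": "chr5",
     "coordinate": "1300", "p_value": "0.20", "bin": "b1"},
    {"SNP_Name": "rs102", "gene": "MLL4", "chromosome": "chr19",
     "coordinate": "510", "p_value": "0.05", "bin": "b2"},
    {"SNP_Name": "rs103", "gene": "FN1", "chromosome": "chr2",
     "coordinate": "900", "p_value": "0.50", "bin": "b1"},
    {"SNP_Name": "rs104", "gene": "TERT", "chromosome": "chrX",
     "coordinate": "77", "p_value": "0.03", "bin": "b2"},
    {"SNP_Name": "rs105", "gene": "CCNE1", "chromosome": "chr19",
     "coordinate": "42", "p_value": "0.90", "bin": "b2"},
]


@pytest.fixture(scope="session")
def fig1_structure():
    return parse_structure_config(FIG1_CONFIG)


@pytest.fixture(scope="session")
def snp_structure():
    return parse_structure_config(SNP_CONFIG)


@pytest.fixture(scope="session")
def snp_table(snp_structure):
    from rdfacets import TableSource
    header = ["SNP_Name", "gene", "chromosome", "coordinate", "p_value", "bin"]
    return TableSource("snps", header, [dict(r) for r in SNP_ROWS])


@pytest.fixture(scope="session")
def snp_engine(snp_table, snp_structure):
    graph, _ = convert_table(snp_table, snp_structure)
    index = build_index(graph, snp_structure)
    return QueryEngine(Store.local(graph), snp_structure, index=index)


@pytest.fixture(scope="session")
def integration_setup():
    """Default-plan integration fixture, converted and indexed once."""
    table, manifest = generate_integration_table()
    structure = hbv_structure()
    graph, report = convert_table(table, structure)
    index = build_index(graph, structure)
    engine = QueryEngine(Store.local(graph), structure, index=index)
    return {"table": table, "manifest": manifest, "structure": structure,
            "graph": graph, "report": report, "engine": engine}


class _SparqlHandler(BaseHTTPRequestHandler):
    graph = None

    def _respond(self, query):
        data = self.graph.query(query).serialize(format="json")
        self.send_response(200)
        self.send_header("Content-Type", "application/sparql-results+json")
        self.send_header("Content-Length", str(len(data)))
        self.end_headers()
        self.wfile.write(data)

    def do_GET(self):
        self._respond(parse_qs(urlparse(self.path).query).get("query", [""])[0])

    def do_POST(self):
        body = self.rfile.read(int(self.headers.get("Content-Length", 0))).decode()
        if "sparql-query" in self.headers.get("Content-Type", ""):
            query = body
        else:
            query = parse_qs(body).get("query", [""])[0]
        self._respond(query)

    def log_message(self, *args):
        pass


@pytest.fixture
def sparql_endpoint():
    """A loopback SPARQL 1.1 protocol endpoint serving a given graph."""
    servers = []

    def start(graph):
        handler = type("Handler", (_SparqlHandler,), {"graph": graph})
        server = HTTPServer(("127.0.0.1", 0), handler)
        threading.Thread(target=server.serve_forever, daemon=True).start()
        servers.append(server)
        return f"http://127.0.0.1:{server.server_port}/sparql"

    yield start
    for server in servers:
        server.shutdown()
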