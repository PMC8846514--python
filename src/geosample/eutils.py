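"""Optional live NCBI eUtils client (esearch/efetch) behind the ingest interface.

A thin stdlib-urllib client for harvesting BioSample metadata and RunInfo at
full scale. It shares the parsing path with :mod:`geosample.ingest`, so a
live harvest and a file-based audit produce identical record objects. The
test suite never touches the network; this module exists so a production
audit can swap file inputs for live queries without changing anything
downstream.
"""

from __future__ import annotations

import io
import time
import urllib.parse
import urllib.request

import pandas as pd

from .ingest import parse_biosample, parse_runinfo
from .records import SampleRecord

EUTILS_BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"


class EUtilsClient:
    """Minimal esearch/efetch client with polite rate limiting."""

    def __init__(self, base_url: str = EUTILS_BASE, delay_s: float = 0.4, tool: str = "geosample"):
        self.base_url = base_url
        self.delay_s = delay_s
        self.tool = tool
        self._last_request = 0.0

    def _get(self, endpoint: str, **params) -> bytes:
        wait = self.delay_s - (time.monotonic() - self._last_request)
        if wait > 0:
            time.sleep(wait)
        params.setdefault("tool", self.tool)
        url = f"{self.base_url}/{endpoint}?{urllib.parse.urlencode(params)}"
        with urllib.request.urlopen(url) as response:
            payload = response.read()
        self._last_request = time.monotonic()
        return payload

    def esearch_biosample(self, term: str, retmax: int = 100000) -> list[str]:
        """BioSample IDs matching a query such as
        ``txid408170[Organism] AND biosample sra[filter] AND "public"[filter]``."""
        from lxml import etree

        payload = self._get("esearch.fcgi", db="biosample", term=term, retmax=retmax)
        tree = etree.fromstring(payload)
        return [el.text for el in tree.iter("Id")]

    def efetch_biosample(self, ids: list[str]) -> list[SampleRecord]:
        payload = self._get("efetch.fcgi", db="biosample", id=",".join(ids))
        return parse_biosample(io.BytesIO(payload))

    def fetch_runinfo(self, term: str) -> pd.DataFrame:
        payload = self._get("efetch.fcgi", db="sra", rettype="runinfo", retmode="csv", term=term)
        return parse_runinfo(io.BytesIO(payload))
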