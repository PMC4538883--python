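{
 "format": "treebase-net-v1",
 "name": "fig2ii",
 "comment": "Not tree-based: antichain {a, c, g1, g2} (leaves a, c plus the two grandparents of b) has four members but there are only three leaves. The parent of b has two out-degree-1 parents.",
 "vertices": [
  {
   "id": "a",
   "label": "a"
  },
  {
   "id": "b",
   "label": "b"
  },
  {
   "id": "c",
   "label": "c"
  },
  {
   "id": "g1"
  },
  {
   "id": "g2"
  },
  {
   "id": "p"
  },
  {
   "id": "rho"
  },
  {
   "id": "s1"
  },
  {
   "id": "s2"
  },
  {
   "id": "s3"
  },
  {
   "id": "s4"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "s1"
  },
  {
   "id": "e01",
   "source": "rho",
   "target": "s2"
  },
  {
   "id": "e02",
   "source": "s1",
   "target": "a"
  },
  {
   "id": "e03",
   "source": "s1",
   "target": "g1"
  },
  {
   "id": "e04",
   "source": "s2",
   "target": "g1"
  },
  {
   "id": "e05",
   "source": "s2",
   "target": "s3"
  },
  {
   "id": "e06",
   "source": "s3",
   "target": "g2"
  },
  {
   "id": "e07",
   "source": "s3",
   "target": "s4"
  },
  {
   "id": "e08",
   "source": "s4",
   "target": "g2"
  },
  {
   "id": "e09",
   "source": "s4",
   "target": "c"
  },
  {
   "id": "e10",
   "source": "g1",
   "target": "p"
  },
  {
   "id": "e11",
   "source": "g2",
   "target": "p"
  },
  {
   "id": "e12",
   "source": "p",
   "target": "b"
  }
 ]
}
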