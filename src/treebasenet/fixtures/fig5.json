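{
 "format": "treebase-net-v1",
 "name": "fig5",
 "comment": "Based on the tree ab|c and displays bc|a but is not based on bc|a: exhibiting bc|a as a base would require the linking arc into h to leave from v, whose other outgoing arc is itself a linking arc.",
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
   "id": "h"
  },
  {
   "id": "p1"
  },
  {
   "id": "q"
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
   "id": "u"
  },
  {
   "id": "v"
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
   "target": "p1"
  },
  {
   "id": "e03",
   "source": "s1",
   "target": "v"
  },
  {
   "id": "e04",
   "source": "s2",
   "target": "p1"
  },
  {
   "id": "e05",
   "source": "s2",
   "target": "u"
  },
  {
   "id": "e06",
   "source": "p1",
   "target": "q"
  },
  {
   "id": "e07",
   "source": "v",
   "target": "q"
  },
  {
   "id": "e08",
   "source": "v",
   "target": "h"
  },
  {
   "id": "e09",
   "source": "u",
   "target": "b"
  },
  {
   "id": "e10",
   "source": "u",
   "target": "h"
  },
  {
   "id": "e11",
   "source": "q",
   "target": "a"
  },
  {
   "id": "e12",
   "source": "h",
   "target": "c"
  }
 ]
}
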