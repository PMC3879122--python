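// parameters
k1 = 0.01;
k2 = 100;
k3 = 1;
l1 = 0.01;
l2 = 100;
l3 = 1;
m1 = 0.01;
m2 = 100;
m3 = 1;
d1 = 0;
d2 = 0.05;
d3 = 0.02426;

// kinetic laws
kineticLawOf r_k1 : fMA(k1);
kineticLawOf r_k2 : fMA(k2);
kineticLawOf r_k3 : fMA(k3);
kineticLawOf r_l1 : fMA(l1);
kineticLawOf r_l2 : fMA(l2);
kineticLawOf r_l3 : fMA(l3);
kineticLawOf r_m1 : fMA(m1);
kineticLawOf r_m2 : fMA(m2);
kineticLawOf r_m3 : fMA(m3);
kineticLawOf r_d1 : fMA(d1);
kineticLawOf r_d2 : fMA(d2);
kineticLawOf r_d3 : fMA(d3);

// species behaviours
A = (r_k1, 1) <<;
B = (r_k3, 1) >> + (r_l1, 1) << + (r_l2, 1) >> + (r_m1, 1) << + (r_m2, 1) >> + (r_m3, 1) >> + (r_d1, 1) <<;
f = (r_k1, 1) << + (r_k2, 1) >> + (r_k3, 1) >> + (r_l3, 1) >> + (r_m1, 1) << + (r_m2, 1) >> + (r_d2, 1) <<;
p = (r_l1, 1) << + (r_l2, 1) >> + (r_l3, 1) >> + (r_m3, 1) >> + (r_d3, 1) <<;
fA = (r_k1, 1) >> + (r_k2, 1) << + (r_k3, 1) <<;
pB = (r_l1, 1) >> + (r_l2, 1) << + (r_l3, 1) <<;
Bf = (r_m1, 1) >> + (r_m2, 1) << + (r_m3, 1) <<;

constant A;

// composition
A[1000] <*> B[0] <*> f[1000] <*> p[0] <*> fA[0] <*> pB[0] <*> Bf[0]
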