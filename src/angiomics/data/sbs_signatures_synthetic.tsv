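Type	SBS1	SBS5	SBS7a	SBS7b	flat
A[C>A]A	0.00052083333	0.011434763	0.00052083333	0.00052083333	0.010416667
A[C>A]C	0.00052083333	0.013450566	0.00052083333	0.00052083333	0.010416667
A[C>A]G	0.00052083333	0.0031420978	0.00052083333	0.00052083333	0.010416667
A[C>A]T	0.00052083333	0.0050170823	0.00052083333	0.00052083333	0.010416667
C[C>A]A	0.00052083333	0.005935207	0.00052083333	0.00052083333	0.010416667
C[C>A]C	0.00052083333	0.0096096918	0.00052083333	0.00052083333	0.010416667
C[C>A]G	0.00052083333	0.0067013598	0.00052083333	0.00052083333	0.010416667
C[C>A]T	0.00052083333	0.0065462354	0.00052083333	0.00052083333	0.010416667
G[C>A]A	0.00052083333	0.0031020988	0.00052083333	0.00052083333	0.010416667
G[C>A]C	0.00052083333	0.0042046144	0.00052083333	0.00052083333	0.010416667
G[C>A]G	0.00052083333	0.0066909709	0.00052083333	0.00052083333	0.010416667
G[C>A]T	0.00052083333	0.0041236878	0.00052083333	0.00052083333	0.010416667
T[C>A]A	0.00052083333	0.029614203	0.00052083333	0.00052083333	0.010416667
T[C>A]C	0.00052083333	0.0053580887	0.00052083333	0.00052083333	0.010416667
T[C>A]G	0.00052083333	0.0026704467	0.00052083333	0.00052083333	0.010416667
T[C>A]T	0.00052083333	0.024216606	0.00052083333	0.00052083333	0.010416667
A[C>G]A	0.00052083333	0.010398835	0.00052083333	0.00052083333	0.010416667
A[C>G]C	0.00052083333	0.0044734098	0.00052083333	0.00052083333	0.010416667
A[C>G]G	0.00052083333	0.0056556651	0.00052083333	0.00052083333	0.010416667
A[C>G]T	0.00052083333	0.023394284	0.00052083333	0.00052083333	0.010416667
C[C>G]A	0.00052083333	0.021591968	0.00052083333	0.00052083333	0.010416667
C[C>G]C	0.00052083333	0.0094401793	0.00052083333	0.00052083333	0.010416667
C[C>G]G	0.00052083333	0.020444499	0.00052083333	0.00052083333	0.010416667
C[C>G]T	0.00052083333	0.03169867	0.00052083333	0.00052083333	0.010416667
G[C>G]A	0.00052083333	0.002272193	0.00052083333	0.00052083333	0.010416667
G[C>G]C	0.00052083333	0.018074026	0.00052083333	0.00052083333	0.010416667
G[C>G]G	0.00052083333	0.014892701	0.00052083333	0.00052083333	0.010416667
G[C>G]T	0.00052083333	0.0010011543	0.00052083333	0.00052083333	0.010416667
T[C>G]A	0.00052083333	0.0088740049	0.00052083333	0.00052083333	0.010416667
T[C>G]C	0.00052083333	0.0019403717	0.00052083333	0.00052083333	0.010416667
T[C>G]G	0.00052083333	0.0051490448	0.00052083333	0.00052083333	0.010416667
T[C>G]T	0.00052083333	0.01367736	0.00052083333	0.00052083333	0.010416667
A[C>T]A	0.00052083333	0.01256104	0.00052083333	0.00052083333	0.010416667
A[C>T]C	0.00052083333	0.01679084	0.00052083333	0.00052083333	0.010416667
A[C>T]G	0.23802083	0.0087871687	0.00052083333	0.00052083333	0.010416667
A[C>T]T	0.00052083333	0.0077077796	0.00052083333	0.00052083333	0.010416667
C[C>T]A	0.00052083333	0.010324464	0.025520833	0.20052083	0.010416667
C[C>T]C	0.00052083333	0.0056012004	0.025520833	0.20052083	0.010416667
C[C>T]G	0.23802083	0.004330665	0.025520833	0.20052083	0.010416667
C[C>T]T	0.00052083333	0.014734949	0.025520833	0.20052083	0.010416667
G[C>T]A	0.00052083333	0.011234638	0.00052083333	0.00052083333	0.010416667
G[C>T]C	0.00052083333	0.008021174	0.00052083333	0.00052083333	0.010416667
G[C>T]G	0.23802083	0.0041629947	0.00052083333	0.00052083333	0.010416667
G[C>T]T	0.00052083333	0.02087711	0.00052083333	0.00052083333	0.010416667
T[C>T]A	0.00052083333	0.017617736	0.21302083	0.038020833	0.010416667
T[C>T]C	0.00052083333	0.023911767	0.21302083	0.038020833	0.010416667
T[C>T]G	0.23802083	0.0053919031	0.21302083	0.038020833	0.010416667
T[C>T]T	0.00052083333	0.010224188	0.21302083	0.038020833	0.010416667
A[T>A]A	0.00052083333	0.0046551191	0.00052083333	0.00052083333	0.010416667
A[T>A]C	0.00052083333	0.0024582853	0.00052083333	0.00052083333	0.010416667
A[T>A]G	0.00052083333	0.0085369321	0.00052083333	0.00052083333	0.010416667
A[T>A]T	0.00052083333	0.0060161452	0.00052083333	0.00052083333	0.010416667
C[T>A]A	0.00052083333	0.014706639	0.00052083333	0.00052083333	0.010416667
C[T>A]C	0.00052083333	0.013123859	0.00052083333	0.00052083333	0.010416667
C[T>A]G	0.00052083333	0.0056970428	0.00052083333	0.00052083333	0.010416667
C[T>A]T	0.00052083333	0.0060508479	0.00052083333	0.00052083333	0.010416667
G[T>A]A	0.00052083333	0.0034548158	0.00052083333	0.00052083333	0.010416667
G[T>A]C	0.00052083333	0.018597807	0.00052083333	0.00052083333	0.010416667
G[T>A]G	0.00052083333	0.0081465722	0.00052083333	0.00052083333	0.010416667
G[T>A]T	0.00052083333	0.011323459	0.00052083333	0.00052083333	0.010416667
T[T>A]A	0.00052083333	0.009418465	0.00052083333	0.00052083333	0.010416667
T[T>A]C	0.00052083333	0.0058121321	0.00052083333	0.00052083333	0.010416667
T[T>A]G	0.00052083333	0.0022607766	0.00052083333	0.00052083333	0.010416667
T[T>A]T	0.00052083333	0.016124703	0.00052083333	0.00052083333	0.010416667
A[T>C]A	0.00052083333	0.021132419	0.00052083333	0.00052083333	0.010416667
A[T>C]C	0.00052083333	0.007627989	0.00052083333	0.00052083333	0.010416667
A[T>C]G	0.00052083333	0.0096189525	0.00052083333	0.00052083333	0.010416667
A[T>C]T	0.00052083333	0.0020209303	0.00052083333	0.00052083333	0.010416667
C[T>C]A	0.00052083333	0.00089667309	0.00052083333	0.00052083333	0.010416667
C[T>C]C	0.00052083333	0.0091600311	0.00052083333	0.00052083333	0.010416667
C[T>C]G	0.00052083333	0.0086896155	0.00052083333	0.00052083333	0.010416667
C[T>C]T	0.00052083333	0.016961257	0.00052083333	0.00052083333	0.010416667
G[T>C]A	0.00052083333	0.0080977702	0.00052083333	0.00052083333	0.010416667
G[T>C]C	0.00052083333	0.00080686367	0.00052083333	0.00052083333	0.010416667
G[T>C]G	0.00052083333	0.026152359	0.00052083333	0.00052083333	0.010416667
G[T>C]T	0.00052083333	0.011195215	0.00052083333	0.00052083333	0.010416667
T[T>C]A	0.00052083333	0.010666497	0.00052083333	0.00052083333	0.010416667
T[T>C]C	0.00052083333	0.0047869392	0.00052083333	0.00052083333	0.010416667
T[T>C]G	0.00052083333	0.0058704597	0.00052083333	0.00052083333	0.010416667
T[T>C]T	0.00052083333	0.0081708658	0.00052083333	0.00052083333	0.010416667
A[T>G]A	0.00052083333	0.001928534	0.00052083333	0.00052083333	0.010416667
A[T>G]C	0.00052083333	0.031824357	0.00052083333	0.00052083333	0.010416667
A[T>G]G	0.00052083333	0.0071282264	0.00052083333	0.00052083333	0.010416667
A[T>G]T	0.00052083333	0.027888808	0.00052083333	0.00052083333	0.010416667
C[T>G]A	0.00052083333	0.02186999	0.00052083333	0.00052083333	0.010416667
C[T>G]C	0.00052083333	0.00059525379	0.00052083333	0.00052083333	0.010416667
C[T>G]G	0.00052083333	0.0053502532	0.00052083333	0.00052083333	0.010416667
C[T>G]T	0.00052083333	0.006757249	0.00052083333	0.00052083333	0.010416667
G[T>G]A	0.00052083333	0.010958486	0.00052083333	0.00052083333	0.010416667
G[T>G]C	0.00052083333	0.012606847	0.00052083333	0.00052083333	0.010416667
G[T>G]G	0.00052083333	0.0090188877	0.00052083333	0.00052083333	0.010416667
G[T>G]T	0.00052083333	0.0048510711	0.00052083333	0.00052083333	0.010416667
T[T>G]A	0.00052083333	0.036406212	0.00052083333	0.00052083333	0.010416667
T[T>G]C	0.00052083333	0.014309301	0.00052083333	0.00052083333	0.010416667
T[T>G]G	0.00052083333	0.0020355397	0.00052083333	0.00052083333	0.010416667
T[T>G]T	0.00052083333	0.0011568433	0.00052083333	0.00052083333	0.010416667
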