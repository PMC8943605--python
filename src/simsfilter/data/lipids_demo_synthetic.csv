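formula,class,name
C12H24O2,FA,FA 12:0
C14H28O2,FA,FA 14:0
C16H32O2,FA,FA 16:0
C16H30O2,FA,FA 16:1
C18H36O2,FA,FA 18:0
C18H34O2,FA,FA 18:1
C18H32O2,FA,FA 18:2
C18H30O2,FA,FA 18:3
C20H40O2,FA,FA 20:0
C20H32O2,FA,FA 20:4
C22H32O2,FA,FA 22:6
C24H48O2,FA,FA 24:0
C27H46O,ST,cholesterol
C27H46O4S,ST,cholesterol sulfate
C43H76O2,ST,CE 16:0
C45H78O2,ST,CE 18:1
C45H76O2,ST,CE 18:2
C40H80NO8P,GP,PC 32:0
C42H82NO8P,GP,PC 34:1
C42H80NO8P,GP,PC 34:2
C44H84NO8P,GP,PC 36:2
C44H80NO8P,GP,PC 36:4
C39H76NO8P,GP,PE 34:1
C41H78NO8P,GP,PE 36:2
C43H78NO8P,GP,PE 38:4
C40H76NO10P,GP,PS 34:1
C47H83O13P,GP,PI 38:4
C24H50NO7P,GP,LPC 16:0
C26H52NO7P,GP,LPC 18:1
C39H79N2O6P,SP,SM d18:1/16:0
C34H67NO3,SP,Cer d18:1/16:0
C18H37NO2,SP,sphingosine d18:1...
C21H40O4,GL,MG 18:1
C39H72O5,GL,DG 36:2
C55H102O6,GL,TG 52:2
C57H104O6,GL,TG 54:3
C30H50,PR,squalene
C29H50O2,PR,alpha-tocopherol
C20H30O,PR,retinal
C40H56,PR,beta-carotene
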