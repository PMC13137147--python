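name,formula,class
PA(32:0),C35H69O8P,PA
PA(32:1),C35H67O8P,PA
PA(32:2),C35H65O8P,PA
PA(32:3),C35H63O8P,PA
PA(32:4),C35H61O8P,PA
PA(34:0),C37H73O8P,PA
PA(34:1),C37H71O8P,PA
PA(34:2),C37H69O8P,PA
PA(34:3),C37H67O8P,PA
PA(34:4),C37H65O8P,PA
PA(36:0),C39H77O8P,PA
PA(36:1),C39H75O8P,PA
PA(36:2),C39H73O8P,PA
PA(36:3),C39H71O8P,PA
PA(36:4),C39H69O8P,PA
PA(38:0),C41H81O8P,PA
PA(38:1),C41H79O8P,PA
PA(38:2),C41H77O8P,PA
PA(38:3),C41H75O8P,PA
PA(38:4),C41H73O8P,PA
PA(40:0),C43H85O8P,PA
PA(40:1),C43H83O8P,PA
PA(40:2),C43H81O8P,PA
PA(40:3),C43H79O8P,PA
PA(40:4),C43H77O8P,PA
PE(32:0),C37H74NO8P,PE
PE(32:1),C37H72NO8P,PE
PE(32:2),C37H70NO8P,PE
PE(32:3),C37H68NO8P,PE
PE(32:4),C37H66NO8P,PE
PE(32:5),C37H64NO8P,PE
PE(32:6),C37H62NO8P,PE
PE(34:0),C39H78NO8P,PE
PE(34:1),C39H76NO8P,PE
PE(34:2),C39H74NO8P,PE
PE(34:3),C39H72NO8P,PE
PE(34:4),C39H70NO8P,PE
PE(34:5),C39H68NO8P,PE
PE(34:6),C39H66NO8P,PE
PE(36:0),C41H82NO8P,PE
PE(36:1),C41H80NO8P,PE
PE(36:2),C41H78NO8P,PE
PE(36:3),C41H76NO8P,PE
PE(36:4),C41H74NO8P,PE
PE(36:5),C41H72NO8P,PE
PE(36:6),C41H70NO8P,PE
PE(38:0),C43H86NO8P,PE
PE(38:1),C43H84NO8P,PE
PE(38:2),C43H82NO8P,PE
PE(38:3),C43H80NO8P,PE
PE(38:4),C43H78NO8P,PE
PE(38:5),C43H76NO8P,PE
PE(38:6),C43H74NO8P,PE
PE(40:0),C45H90NO8P,PE
PE(40:1),C45H88NO8P,PE
PE(40:2),C45H86NO8P,PE
PE(40:3),C45H84NO8P,PE
PE(40:4),C45H82NO8P,PE
PE(40:5),C45H80NO8P,PE
PE(40:6),C45H78NO8P,PE
PI(32:0),C41H79O13P,PI
PI(32:1),C41H77O13P,PI
PI(32:2),C41H75O13P,PI
PI(32:3),C41H73O13P,PI
PI(32:4),C41H71O13P,PI
PI(32:5),C41H69O13P,PI
PI(32:6),C41H67O13P,PI
PI(34:0),C43H83O13P,PI
PI(34:1),C43H81O13P,PI
PI(34:2),C43H79O13P,PI
PI(34:3),C43H77O13P,PI
PI(34:4),C43H75O13P,PI
PI(34:5),C43H73O13P,PI
PI(34:6),C43H71O13P,PI
PI(36:0),C45H87O13P,PI
PI(36:1),C45H85O13P,PI
PI(36:2),C45H83O13P,PI
PI(36:3),C45H81O13P,PI
PI(36:4),C45H79O13P,PI
PI(36:5),C45H77O13P,PI
PI(36:6),C45H75O13P,PI
PI(38:0),C47H91O13P,PI
PI(38:1),C47H89O13P,PI
PI(38:2),C47H87O13P,PI
PI(38:3),C47H85O13P,PI
PI(38:4),C47H83O13P,PI
PI(38:5),C47H81O13P,PI
PI(38:6),C47H79O13P,PI
PI(40:0),C49H95O13P,PI
PI(40:1),C49H93O13P,PI
PI(40:2),C49H91O13P,PI
PI(40:3),C49H89O13P,PI
PI(40:4),C49H87O13P,PI
PI(40:5),C49H85O13P,PI
PI(40:6),C49H83O13P,PI
PS(32:0),C38H74NO10P,PS
PS(32:1),C38H72NO10P,PS
PS(32:2),C38H70NO10P,PS
PS(32:3),C38H68NO10P,PS
PS(32:4),C38H66NO10P,PS
PS(34:0),C40H78NO10P,PS
PS(34:1),C40H76NO10P,PS
PS(34:2),C40H74NO10P,PS
PS(34:3),C40H72NO10P,PS
PS(34:4),C40H70NO10P,PS
PS(36:0),C42H82NO10P,PS
PS(36:1),C42H80NO10P,PS
PS(36:2),C42H78NO10P,PS
PS(36:3),C42H76NO10P,PS
PS(36:4),C42H74NO10P,PS
PS(38:0),C44H86NO10P,PS
PS(38:1),C44H84NO10P,PS
PS(38:2),C44H82NO10P,PS
PS(38:3),C44H80NO10P,PS
PS(38:4),C44H78NO10P,PS
PS(40:0),C46H90NO10P,PS
PS(40:1),C46H88NO10P,PS
PS(40:2),C46H86NO10P,PS
PS(40:3),C46H84NO10P,PS
PS(40:4),C46H82NO10P,PS
PG(32:0),C38H75O10P,PG
PG(32:1),C38H73O10P,PG
PG(32:2),C38H71O10P,PG
PG(32:3),C38H69O10P,PG
PG(34:0),C40H79O10P,PG
PG(34:1),C40H77O10P,PG
PG(34:2),C40H75O10P,PG
PG(34:3),C40H73O10P,PG
PG(36:0),C42H83O10P,PG
PG(36:1),C42H81O10P,PG
PG(36:2),C42H79O10P,PG
PG(36:3),C42H77O10P,PG
PG(38:0),C44H87O10P,PG
PG(38:1),C44H85O10P,PG
PG(38:2),C44H83O10P,PG
PG(38:3),C44H81O10P,PG
PG(40:0),C46H91O10P,PG
PG(40:1),C46H89O10P,PG
PG(40:2),C46H87O10P,PG
PG(40:3),C46H85O10P,PG
LPE(16:0),C21H44NO7P,LPE
LPE(16:1),C21H42NO7P,LPE
LPE(16:2),C21H40NO7P,LPE
LPE(18:0),C23H48NO7P,LPE
LPE(18:1),C23H46NO7P,LPE
LPE(18:2),C23H44NO7P,LPE
LPE(20:0),C25H52NO7P,LPE
LPE(20:1),C25H50NO7P,LPE
LPE(20:2),C25H48NO7P,LPE
LPE(22:0),C27H56NO7P,LPE
LPE(22:1),C27H54NO7P,LPE
LPE(22:2),C27H52NO7P,LPE
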